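"""Modes of life and functional (ecospace) abundance tables.

A mode of life is the triple (tiering, motility, feeding) of a genus in a
Bambach-style ecospace.  Category vocabularies are configuration, not code:
the shipped ``data/ecospace_categories.yaml`` defines the default closed
sets, and users may point the loader at their own vocabulary file.

Tallying congeneric abundances into functional groups turns a genus-rank
:class:`~paleocomm.occurrences.AbundanceTable` into a functional-rank one;
specimen totals are conserved when every genus is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .occurrences import AbundanceTable, ValidationError, _canon, _key


@dataclass(frozen=True)
class ModeOfLife:
    tiering: str
    motility: str
    feeding: str

    @property
    def label(self) -> str:
        return f"{self.tiering}|{self.motility}|{self.feeding}"


def load_vocabulary(path=None) -> dict[str, tuple[str, ...]]:
    """Load category vocabularies; defaults to the shipped YAML."""
    if path is None:
        text = resources.files("paleocomm.data").joinpath(
            "ecospace_categories.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    vocab = {}
    for axis in ("tiering", "motility", "feeding"):
        if axis not in raw:
            raise ValidationError(f"vocabulary lacks axis {axis!r}")
        vocab[axis] = tuple(str(v) for v in raw[axis])
    return vocab


class EcospaceAssignment:
    """Validated mapping genus -> :class:`ModeOfLife`."""

    def __init__(self, mapping: dict[str, ModeOfLife],
                 vocabulary: dict[str, tuple[str, ...]] | None = None):
        self.vocabulary = vocabulary or load_vocabulary()
        self._map: dict[str, ModeOfLife] = {}
        for genus, mol in mapping.items():
            self._validate(genus, mol)
            self._map[_key(genus)] = mol

    def _validate(self, genus: str, mol: ModeOfLife) -> None:
        for axis in ("tiering", "motility", "feeding"):
            val = getattr(mol, axis)
            if val not in self.vocabulary[axis]:
                raise ValidationError(
                    f"{genus}: unknown {axis} category {val!r}")
        k = _key(genus)
        if k in self._map and self._map[k] != mol:
            raise ValidationError(f"conflicting mode of life for genus {genus!r}")

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, genus: str) -> bool:
        return _key(genus) in self._map

    def get(self, genus: str) -> ModeOfLife | None:
        return self._map.get(_key(genus))

    def n_functional_groups(self) -> int:
        """Number of distinct modes of life realised in the assignment."""
        return len(set(self._map.values()))

    def items(self):
        return self._map.items()


def load_ecospace(path, vocabulary_path=None) -> EcospaceAssignment:
    """Read an assignment CSV with columns genus, tiering, motility, feeding.

    Duplicate genus rows must agree; a conflicting duplicate or a category
    outside the vocabulary raises :class:`ValidationError`.
    """
    vocab = load_vocabulary(vocabulary_path)
    df = pd.read_csv(path, skipinitialspace=True)
    missing = {"genus", "tiering", "motility", "feeding"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    mapping: dict[str, ModeOfLife] = {}
    seen: dict[str, ModeOfLife] = {}
    for _, row in df.iterrows():
        genus = _canon(row["genus"])
        mol = ModeOfLife(_canon(row["tiering"]), _canon(row["motility"]),
                         _canon(row["feeding"]))
        k = _key(genus)
        if k in seen and seen[k] != mol:
            raise ValidationError(f"{path}: conflicting rows for genus {genus!r}")
        seen[k] = mol
        mapping[genus] = mol
    return EcospaceAssignment(mapping, vocab)


def write_ecospace(assign: EcospaceAssignment, path) -> None:
    rows = [(g, m.tiering, m.motility, m.feeding) for g, m in sorted(assign.items())]
    pd.DataFrame(rows, columns=["genus", "tiering", "motility", "feeding"]).to_csv(
        path, index=False)


def to_functional_table(table: AbundanceTable, assign: EcospaceAssignment,
                        on_missing: str = "error") -> AbundanceTable:
    """Tally genus abundances into functional-group columns.

    With ``on_missing="error"`` an unassigned genus aborts the tally (the
    default, forcing explicit curation); with ``"drop"`` unassigned genera
    are removed before tallying.
    """
    if table.rank != "genus":
        raise ValidationError("functional tallying requires a genus-rank table")
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    labels = {}
    unassigned = []
    for genus in table.taxa:
        mol = assign.get(genus)
        if mol is None:
            unassigned.append(genus)
        else:
            labels[genus] = mol.label
    if unassigned:
        if on_missing == "error":
            raise ValidationError(
                f"genera without mode-of-life assignment: {sorted(unassigned)[:10]}")
        table = AbundanceTable(
            table.counts.drop(columns=unassigned), table.meta, None,
            "genus", table.scheme).drop_empty_taxa()
    func = table.counts.T.groupby(
        pd.Index([labels[g] for g in table.taxa])).sum().T
    func = func[sorted(func.columns)]
    return AbundanceTable(func, table.meta, None, "functional", table.scheme)
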