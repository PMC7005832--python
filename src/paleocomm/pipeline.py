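"""End-to-end analysis pipeline.

``run`` executes the full Methods-style sequence on one dataset:
filtering -> genus aggregation -> (optional) functional tallying ->
raw + coverage-subsampled richness -> Foote turnover rates ->
dissimilarities -> nMDS -> sequential PERMANOVA -> unipartite walktrap +
bipartite COPRA networks with a configuration-model null test ->
(optional) latitudinal affinity composition.  Every stage writes its
interface table into the output directory and the run report records
seeds, configuration and the counts at each filter so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import AffinityScheme, bin_affinity_composition, classify_all, load_lat_ranges, LatRangeRecord
from .composition import dissimilarity_matrix, nmds, sequential_centroid_dissimilarity
from .diversity import SQSConfig, richness_table
from .ecospace import load_ecospace, to_functional_table
from .networks import (
    best_of_n,
    build_bipartite,
    build_unipartite,
    detect_walktrap_score,
    extended_modularity,
    null_modularity_test,
    project_bipartite,
    walktrap,
    write_edge_list,
    write_membership,
)
from .occurrences import (
    aggregate_to_rank,
    filter_min_specimens,
    load_abundance_table,
    write_long_csv,
)
from .synthetic import preset, simulate
from .turnover import rate_series

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully explicit pipeline configuration (see pipeline docstring)."""

    out_dir: str = "paleocomm_run"
    # input: either a synthetic preset or file paths
    synthetic_preset: str | None = "stable"
    synthetic_overrides: dict = field(default_factory=dict)
    abundance_path: str | None = None
    abundance_format: str = "long_csv"
    ecospace_path: str | None = None
    lat_ranges_path: str | None = None
    # stage parameters
    min_specimens: int = 50
    sqs_quota: float = 0.6
    sqs_trials: int = 200
    nmds_stress_threshold: float = 0.3
    nmds_prefilter_threshold: float = 0.8
    nmds_restarts: int = 4
    n_permutations: int = 999
    copra_runs: int = 200
    copra_v: int = 2
    walktrap_steps: int = 5
    null_n_random: int = 0          # 0 disables the (slow) null test
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__,
                    "config": dataclasses.asdict(config), "stages": {}}
    rng_seed = config.seed

    try:
        # ---- load or simulate -------------------------------------------
        truth = None
        if config.abundance_path:
            table = load_abundance_table(config.abundance_path,
                                         config.abundance_format)
            ecospace = load_ecospace(config.ecospace_path) if config.ecospace_path else None
            lat_records = (load_lat_ranges(config.lat_ranges_path)
                           if config.lat_ranges_path else None)
        else:
            cfg = preset(config.synthetic_preset or "stable", seed=rng_seed)
            if config.synthetic_overrides:
                cfg = dataclasses.replace(cfg, **config.synthetic_overrides)
            table, truth = simulate(cfg)
            truth.to_json(out / "truth.json")
            ecospace = truth.ecospace
            lat_records = [LatRangeRecord(r.species, r.min_palaeolat, r.max_palaeolat)
                           for r in truth.lat_ranges.itertuples()]
        report["stages"]["load"] = {
            "n_samples": table.n_samples, "n_taxa": table.n_taxa,
            "n_specimens": table.grand_total,
        }

        # ---- filter ------------------------------------------------------
        filtered = filter_min_specimens(table, config.min_specimens)
        report["stages"]["filter"] = {
            "threshold": config.min_specimens,
            "n_samples_before": table.n_samples,
            "n_samples_after": filtered.n_samples,
        }
        write_long_csv(filtered, out / "abundance_filtered.csv")

        genus = aggregate_to_rank(filtered, "genus")
        tables = {"species": filtered, "genus": genus}
        if ecospace is not None:
            tables["functional"] = to_functional_table(genus, ecospace,
                                                       on_missing="drop")
        report["stages"]["ranks"] = {r: t.n_taxa for r, t in tables.items()}

        # ---- diversity ---------------------------------------------------
        sqs_cfg = SQSConfig(config.sqs_quota, config.sqs_trials, seed=rng_seed)
        rich = richness_table(tables, sqs_cfg)
        rich.to_csv(out / "richness.tsv", sep="\t", index=False)
        report["stages"]["diversity"] = {
            f"mean_sqs_{r}": float(np.nanmean(rich[f"sqs_{r}"])) for r in tables
        }

        # ---- turnover ----------------------------------------------------
        turnover_report = {}
        for rank in ("species", "genus"):
            rates = rate_series(tables[rank])
            rates.to_csv(out / f"foote_rates_{rank}.tsv", sep="\t")
            interior = rates["extinction"].dropna()
            turnover_report[rank] = {
                "max_extinction_bin": (int(interior.idxmax())
                                       if len(interior) else None),
                "max_extinction": (float(interior.max())
                                   if len(interior) else None),
            }
        report["stages"]["turnover"] = turnover_report

        # ---- composition -------------------------------------------------
        comp_report = {}
        bins = dict(zip(tables["genus"].sample_ids,
                        tables["genus"].meta["time_bin"]))
        for rank in tables:
            d_bc = dissimilarity_matrix(tables[rank], "bray_curtis")
            ord_res = nmds(
                d_bc, k=2, n_restarts=config.nmds_restarts, seed=rng_seed,
                stress_threshold=config.nmds_stress_threshold,
                prefilter_threshold=(config.nmds_prefilter_threshold
                                     if rank == "species" else None))
            ord_res.to_frame().to_csv(out / f"nmds_{rank}.tsv", sep="\t")
            seq = sequential_centroid_dissimilarity(
                d_bc, bins, n_permutations=config.n_permutations, seed=rng_seed)
            seq.to_csv(out / f"permanova_sequential_{rank}.tsv", sep="\t",
                       index=False)
            d_k = dissimilarity_matrix(tables[rank], "kulczynski_pa")
            seq_k = sequential_centroid_dissimilarity(
                d_k, bins, n_permutations=config.n_permutations, seed=rng_seed)
            seq_k.to_csv(out / f"permanova_sequential_{rank}_pa.tsv", sep="\t",
                         index=False)
            comp_report[rank] = {
                "stress": ord_res.stress,
                "n_excluded": len(ord_res.excluded),
                "max_t": float(seq["t"].max()) if len(seq) else None,
                "max_t_bin": (int(seq.loc[seq["t"].idxmax(), "bin"])
                              if len(seq) else None),
            }
        report["stages"]["composition"] = comp_report

        # ---- networks ----------------------------------------------------
        net_report = {}
        for rank in ("species", "genus"):
            g = build_unipartite(tables[rank])
            part = walktrap(g, steps=config.walktrap_steps)
            write_edge_list(g, out / f"unipartite_{rank}.tsv")
            write_membership(part, out / f"walktrap_{rank}.tsv")
            entry = {"n_modules": part.n_modules,
                     "modularity": part.modularity}
            if config.null_n_random:
                null = null_modularity_test(
                    g, detect_walktrap_score,
                    n_random=config.null_n_random, seed=rng_seed)
                entry["null_fraction_exceeding"] = null.fraction_exceeding
            bip = build_bipartite(tables[rank])
            proj = project_bipartite(bip, "sample")
            cover, summary = best_of_n(
                bip, config.copra_runs,
                quality=lambda c: extended_modularity(proj, _restrict(c, proj)),
                seed=rng_seed, v=config.copra_v)
            write_membership(cover, out / f"copra_{rank}.tsv")
            summary.to_csv(out / f"copra_{rank}_scores.tsv", sep="\t", index=False)
            entry["copra_modules"] = _restrict(cover, proj).n_modules
            entry["extended_modularity"] = cover.extended_modularity
            net_report[rank] = entry
        report["stages"]["networks"] = net_report

        # ---- affinity ----------------------------------------------------
        if lat_records:
            classes = classify_all(lat_records, AffinityScheme())
            comp = bin_affinity_composition(tables["species"], classes)
            comp.to_csv(out / "affinity_composition.tsv", sep="\t")
            report["stages"]["affinity"] = {
                "n_classified": len(classes),
                "labels": sorted(set(classes.values())),
            }
    except Exception as e:
        stage = max(report["stages"], default="load")
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def _restrict(cover, proj):
    """Cover restricted to projection nodes (sample-side scoring)."""
    from .networks import CommunityCover
    nodes = set(proj.nodes)
    bel = {n: dict(c) for n, c in cover.belonging.items() if n in nodes}
    return CommunityCover(bel)
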