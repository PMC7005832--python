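# Closed category vocabularies for the Bambach-style ecospace model used to
# assign genera to modes of life (tiering x motility x feeding).  Edit or
# replace this file to extend the vocabularies; the loader validates every
# assignment against these sets.
tiering:
  - epifaunal
  - erect
  - semi-infaunal
  - shallow-infaunal
  - deep-infaunal
motility:
  - motile
  - facultatively-motile
  - non-motile
feeding:
  - suspension
  - deposit
  - grazer
  - predator
  - scavenger
  - chemosymbiotic
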