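# morphoclade

Maximum-parsimony inference and morphometric seriation toolkit for
fragmentary vertebrate skeletal material. It packages, as one tested
pipeline, the quantitative workflow typical of a theropod redescription:

* **matrix_io** — discrete morphological character matrices: TNT `xread`
  and NEXUS `CHARACTERS` parsing/writing (missing `?` and inapplicable `-`
  kept distinct, bracketed polymorphisms, `ccode` ordering/activation/
  weights), plus the matrix-merge protocol (drop characters, drop taxa,
  concatenate blocks over a harmonised taxon set).
* **parsimony** — Fitch/Hartigan tree length (exact on polytomies; ordered
  characters via a linear-cost dynamic program), random-addition + NNI/SPR/
  TBR heuristic search with equal-length plateau collection, strict
  consensus, maximum agreement subtree (exact ≤ 12 leaves, greedy beyond),
  character-resampling bootstrap, reverse-constraint Bremer decay, ensemble
  CI/RI, and MPR-exact synapomorphy mapping (ACCTRAN / DELTRAN /
  unambiguous-only).
* **morphometrics** — tooth/ungual measurement records with derived ratios
  (CBR, CHR), completeness filtering, covariance/correlation PCA with a
  deterministic loading-sign convention, convex-hull morphospace
  membership, dentary alveolus profiles, and standardized nearest-specimen
  lookup in curvature-vs-length space.
* **caudal_series** — the Anterior Surface Index (ASI = anterior facet
  area / centrum length², dimensionless), anchor-based %ASI and %length
  profiles, descending-ASI series ordering, and template position
  assignment by a monotone minimal-|Δ%ASI| dynamic-programming alignment
  under last-diapophysis constraints.
* **synthetic_data** — seeded generators for character matrices evolved on
  a known tree (homoplasy-free or Poisson), decaying caudal series with
  multiplicative noise, and grouped measurement tables with a shared size
  factor (size-dominated PC1).
* **pipeline_cli** — YAML-config orchestration of all stages with a
  machine-readable JSON report.

## CLI

```sh
morphoclade matrix in.tnt --drop-chars 3,7 --merge other.tnt --out-format nexus -o merged.nex
morphoclade phylo run matrix.tnt --replicates 100 --swapper TBR --seed 1
morphoclade phylo consensus trees.nwk        # strict consensus
morphoclade phylo mast trees.nwk             # maximum agreement subtree
morphoclade phylo bootstrap matrix.tnt --reps 1000 --seed 1
morphoclade phylo bremer matrix.tnt --max-decay 10 --seed 1
morphoclade phylo synapo matrix.tnt tree.nwk --mode unambiguous
morphoclade phylo prune matrix.tnt TaxonA --seed 1
morphoclade morpho teeth-pca teeth.csv --without-al --scaling covariance-raw
morphoclade morpho alveoli alveoli.csv SPEC-1
morphoclade morpho claw-nn claws.csv --curvature 25 --length 120
morphoclade caudal order vertebrae.csv
morphoclade caudal assign vertebrae.csv --template template.csv --template-taxon Spinosaurus
morphoclade simulate matrix --taxa 8 --characters 200 --seed 1 -o sim.tnt
morphoclade run config.yaml                  # full pipeline
```

### Table formats (CSV)

* teeth: `specimen_id, group, CBL, CBW, CH, AL` (mm; AL optional; CBR/CHR
  are derived, never stored)
* unguals: `specimen_id, group, total_length, proximal_ml_diameter,
  proximal_dv_diameter, midlength_ml_diameter, midlength_dv_diameter,
  curvature_deg`
* claw compilation: `specimen_id, curvature_deg, length_mm`
* alveoli: `specimen_id, position, mesiodistal_diameter,
  labiolingual_diameter, height_labial, height_lingual`
* vertebrae: `vertebra_id, centrum_length, facet_dv_diameter,
  facet_ml_diameter, facet_area, has_diapophysis, anchor_flag`
  (give `facet_area` directly or both diameters; the ellipse model is the
  default and only rescales all ASI values by π/4, so %ASI is unaffected)
* templates: `taxon, position, pct_asi, pct_length`

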