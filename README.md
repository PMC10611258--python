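# somaxon

Two-compartment, image-based neurotoxicity scoring for chemotherapy-induced
peripheral neuropathy (CIPN) screening.

Anticancer drugs damage peripheral sensory neurons in compartment-specific
ways: platinum compounds primarily injure the cell body (soma), vinca
alkaloids the axon, taxanes both. When sensory neurons are cultured in a
microphysiological device that physically separates somata from their
neurites, each compartment can be imaged and scored on its own, and the pair
of scores reads out the compound's mechanism of action (MoA). `somaxon`
implements that analysis end to end for anyone who wants to study, extend or
stress-test it without access to proprietary micrographs: a seeded synthetic
image generator stands in for the microscope, and everything downstream is
the real analysis.

## The method

For each compartment a small convolutional network classifies fixed-size
image tiles as *positive* (damage-like) or *negative*, trained with **weak
labels**: every tile of an image inherits the treatment label of the whole
image (vehicle/negative compound → negative, toxicant → positive). Soma
local images are first split into 4 quadrant segments; each segment is cut
into a 6 × 6 grid of tiles (36 tiles per segment), and each segment is one
statistical sample. Axon local images are cut directly into a 4 × 4 grid
(16 tiles, one sample per image).

The per-sample statistic is the **toxicity probability**

```
P_tox = 100 · (# positive tiles) / (# tiles)   [%]
```

and the per-compartment decision threshold is the **toxicity prediction
line** derived from negative controls,

```
line = mean(P_tox over vehicle + negative-compound samples) + 2 · SD,
```

with one-way ANOVA followed by Dunnett's many-to-one test against the
vehicle for per-condition significance. The two compartment scores are then
combined into points (x = axon %, y = soma %); exceedance of the two lines
classifies the MoA (`none`, `soma-dominant`, `axon-dominant`, `mixed`), and
two-group MANOVA (Wilks' Λ) tests pairwise separation of compounds.
Grad-CAM maps show which tile regions drive each classification.

Dunnett's adjusted p-values are computed by deterministic quadrature over
the one-factor correlation structure of the comparison statistics (exact to
< 1e-6; validated against R's `mvtnorm` and against the two-sample t-test
in the single-treatment case).

## Worked example

Run the default study (the compound panel and per-condition sample sizes of
a published CIPN screen: DMSO vehicle, sucrose negative, oxaliplatin,
vincristine, paclitaxel, suramin, bortezomib at two concentrations each) at
quarter scale:

```
somaxon run --seed 0 --out runs/demo
```

which prints, after about three minutes:

```
report written to runs/demo/report.json
  soma toxicity line: 4.94%
  axon toxicity line: 20.14%
```

The lines are the decision thresholds each compartment's negative controls
imply: e.g. an axon sample is flagged only if more than 20.14% of its tiles
look damaged (DMSO and sucrose score 1.0 ± 1.0% and 8.3 ± 8.3% here —
healthy fields are not pristine, and the line absorbs that background).

`runs/demo/moa_calls.csv` then contains the recovered mechanisms:

```
compound,concentration,category
DMSO,0.1%,none
sucrose,10 uM,none
oxaliplatin,10 uM,soma-dominant
oxaliplatin,100 uM,soma-dominant
vincristine,0.003 uM,axon-dominant
vincristine,0.03 uM,axon-dominant
paclitaxel,0.1 uM,mixed
paclitaxel,1 uM,mixed
suramin,10 uM,mixed
suramin,100 uM,mixed
bortezomib,0.01 uM,mixed
```

i.e. the vehicle and the negative compound stay under both lines, the
soma-directed toxicant shifts along the y-axis only, the axon-directed
toxicant along the x-axis only, and the dual toxicants move diagonally —
the quadrant structure the two-compartment design is meant to expose.
`summary_{soma,axon}.csv` hold the per-condition mean ± SEM scores,
`manova_pairwise.csv` the pairwise separation p-values, `moa_plot.png` the
2D scatter with both lines, and `explain/` Grad-CAM overlays (blue =
negative-class focus, magenta = damage focus).

Other subcommands (`simulate`, `train`, `score`, `integrate`, `explain`)
expose the individual stages; `somaxon run --config cfg.yaml` replays a
fully specified configuration. Exact numbers depend on the seed; every
stage is deterministic given the config, and rerunning a config reproduces
identical per-stage content hashes (recorded in `report.json`).

## Layout

- `src/somaxon/phenotypes.py` — damage parameterization, compound profiles, study designs
- `src/somaxon/simulate.py` — seeded synthetic soma/axon image generator
- `src/somaxon/images.py`, `tiling.py` — containers, TIFF/manifest IO, tiling schemes
- `src/somaxon/nn.py`, `classifier.py` — numpy CNN and the weak-label tile classifier
- `src/somaxon/scoring.py`, `stats.py` — toxicity probability, lines, ANOVA + Dunnett, Wilks' Λ
- `src/somaxon/moa.py` — 2D integration, MoA calls, pairwise MANOVA, plotting
- `src/somaxon/gradcam.py` — attention maps and overlays
- `src/somaxon/pipeline.py`, `cli.py` — config-driven end-to-end runs

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
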