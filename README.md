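# mgquant

Quantification pipeline for microglial imaging and slice electrophysiology,
bundled with seeded synthetic-data generators that carry ground truth for
every input. It covers five bespoke analyses:

- **calcium** — ΔF/F normalisation, shape-preserving (PCHIP) baseline fit
  over 100-frame blocks, transient detection at 2.25× the quiescent-frame
  SD with a 0.15 ΔF/F·s minimum-area filter, event rates per 300 s, and
  lesion-evoked peak responses against a 20-s pre-stimulus baseline.
- **puncta** — rolling-ball background subtraction (10 px), fixed
  inclusive intensity thresholds (pre 15–255, post 30–255), 8-connected
  particle analysis with 0.05–1.2 µm² size exclusion, overlap-defined
  synapse counting, engulfed presynaptic area per labelled cell, and area
  fractions.
- **phagocytosis** — bead-to-cell assignment by centroid-in-mask lookup at
  the nearest z-plane (2-µm steps), per-FOV phagocytic index (% cells with
  ≥ `min_beads` beads) and FOV-occurrence summaries.
- **spatial** — soma density (cells/mm²), nearest-neighbour distances and
  the regularity index (mean NND / SD NND), with an optional toroidal
  metric for validating against the 2D-Poisson closed form 1/√(4/π − 1).
- **ephys** — PSC event detection on 2-kHz zero-phase-filtered 20-kHz
  traces, event-frequency comparison across TTX windows (180 s baseline
  vs 180 s starting 100 s post-onset), Gaussian-histogram holding-current
  fits on 20-s segments, agonist-induced current shifts, and Nernst
  reversal potentials derived from solution recipes by chloride
  stoichiometry.

The `synth` subpackage generates each input type (ΔF/F traces, two-channel
punctate images, labelled cell/bead z-stacks, point patterns, current
traces) from a frozen spec with an integer seed; identical spec + seed is
bit-identical, and every generator returns the ground truth used to build
its output.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(analytic targets, closed-form limits, oracle equivalence, parameter
recovery); `tests/oracles.py` contains the independent brute-force oracles.

## CLI

```sh
mgquant --config config.yaml --seed 1 --out-dir results all
```

Verbs: `simulate`, `calcium`, `puncta`, `phago`, `spatial`, `ephys`,
`aggregate`, `all`. The config is a single YAML file; unset fields take
the documented defaults and the fully resolved parameter set is recorded,
with input checksums and seeds, in `results/manifest.json`. Outputs are
CSV tables (per-ROI event tables, synapse reports, phagocytosis reports,
spatial reports, event lists) plus TIFF images for simulated fields.
`aggregate` averages per-image rows to per-slice and per-animal means
(the animal is the terminal statistical unit).

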