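# smtrack

Single-molecule co-tracking analysis for membrane-tethered mRNA imaging:
measure when, how often, and for how long a fluorescently tagged protein
factor sits on individual translating mRNAs, and what that does to
translation.

The package targets TIRF experiments in which reporter mRNAs are tethered
to the plasma membrane (MS2/MCP), translation sites are visualized through
nascent-peptide epitope arrays (SunTag/scFv), and a protein of interest —
a phage coat protein binding 1x/3x/12x stem-loops as a calibration ladder,
or an endogenously HaloTag-labeled E3 ubiquitin ligase of the
ribosome-collision surveillance pathway — is imaged in a third channel.
Because no public raw movies accompany such experiments, every stage ships
with a ground-truthed synthetic generator that emulates the assay, so the
whole pipeline is verifiable end to end.

## What it computes

- **Spot detection** (`smtrack.detection`): Laplacian-of-Gaussian
  band-pass, local-maximum candidates, pixel-integrated 2D/3D elliptical
  Gaussian fits. Integrated intensity is the analytic Gaussian volume
  `2π·A·σx·σy` (× `√(2π)·σz` in 3D).
- **Tracking** (`smtrack.tracking`): gated linear-assignment linking, gap
  closing, track filters (mRNA tracks < 25 frames discarded, protein
  tracks < 4 frames discarded, ≥ 2 min imaging, crossing mRNA paths
  excluded).
- **Colocalization** (`smtrack.colocalization`): protein/translation-site
  tracks join an mRNA when within 1.5 px for ≥ 4 overlapping frames
  (≥ 2 in runoff/UV mode); a colocalization event needs ≥ 5 consecutive
  frames (~10 s; 2 frames at 10-s intervals in runoff/UV mode); per-cell
  fractions honor the cell-eligibility rules (> 15 mRNAs, or > 10
  translating mRNAs).
- **Binding-state segmentation** (`smtrack.segmentation`): bound states as
  colocalization runs lasting ≥ 8 s, or recursive two-sample-t
  change-point segmentation of intensity traces; residence-time statistics
  (arithmetic mean, or a discretization-corrected geometric MLE
  `τ = −Δt / ln(1 − 1/n̄)`); stoichiometry normalization against the
  1x-site calibration mean; KS and pooled-variance t tests.
- **Runoff survival** (`smtrack.runoff`): per-mRNA clearance time — time
  from the translation-site maximum to its first drop below 10% of
  maximum after a translation-initiation block — with the exclusion rules
  (not translating at start; mRNA/TLS loss coincident within ≤ 3 frames),
  Kaplan–Meier curves with Greenwood variance
  `Var Ŝ(t) = Ŝ(t)² Σ d_i / (n_i (n_i − d_i))` and 95% bounds.
- **smFISH-IF quantification** (`smtrack.smfish`): 3D translation-site
  detection near mRNA spots, per-cell single-protein unit intensity, and
  nascent-peptide counts NAP = TLS intensity / unit intensity.
- **Synthetic data** (`smtrack.synthetic`, `smtrack.presets`,
  `smtrack.render`): trace-level and rendered-movie cohorts with known
  binding kinetics, runoff ramps with a damaged subpopulation, and 3D
  smFISH fields, all bit-reproducible per seed.

## Worked example

Measure the residence time of a single binder on 1x-stem-loop mRNAs from
a simulated steady-state experiment (2-s frames, 5-min movies):

```python
import numpy as np
from smtrack import (simulate_binding_cohort, cohort_to_tracks,
                     get_kinetic_preset, LinkParams, LinkRules)
from smtrack.tracking import filter_tracks
from smtrack.colocalization import build_records
from smtrack.segmentation import (bound_segments_from_record,
                                  residence_time_stats)

cohort = simulate_binding_cohort(get_kinetic_preset("pbs_1x_kinetics"),
                                 n_mrna=200, window_s=300.0, dt_s=2.0,
                                 seed=7)
tracks = cohort_to_tracks(cohort, seed=8)
params = LinkParams.steady_state(min_len_protein=1)
for chan in tracks:
    filter_tracks(tracks[chan], params, "steady_state", 2.0)
rules = LinkRules.steady_state(min_overlap_frames_link=1)
records = build_records(tracks["mrna"], tracks["protein"],
                        tracks["tls"], rules, 2.0)
segments = []
for rec in records:
    segments.extend(bound_segments_from_record(rec, 2.0, min_bound_s=0.0))
stats = residence_time_stats(segments, 2.0, policy="geometric")
print(f"episodes: {stats.n}")
print(f"mean residence time: {stats.mean_s:.2f} s")
true = np.mean([e.duration_s for e in cohort.truth.episodes])
print(f"ground-truth mean:   {true:.2f} s")
```

Output:

```
episodes: 232
mean residence time: 3.54 s
ground-truth mean:   3.69 s
```

The 232 bound episodes found by the detect→track→link→segment chain give
a corrected mean dwell of 3.54 s against this cohort's ground-truth draw
of 3.69 s (the preset's population mean is 3.6 s); the difference is
within the estimator's sampling error at this cohort size.

## Command line

```bash
smtrack simulate --kind binding --preset pbs_1x --n 20 --seed 1 --out sim/
smtrack detect sim/mrna.tif --log-sigma 1.3 --out spots.csv
smtrack track spots.csv --mode steady_state --out tracks.csv
smtrack run --config run.yaml     # full configured pipeline + report
```

`smtrack run` executes simulate→detect→track→link→segment (or the runoff
/ smFISH chains) from a single YAML config, writes `tracks.csv`,
`linked.csv`, `cells.csv`, `segments.csv`, `residence.csv` (or
`clearance.csv`/`survival.csv`, `tls.csv`), stamps every table with the
config hash, and reproduces identical outputs on rerun.

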