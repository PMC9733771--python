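# msfusion

Analysis of error-related brain states from simultaneous EEG + fNIRS
recordings, built around two ideas:

1. **EEG microstates** — the scalp potential field is modelled as a
   sequence of quasi-stable (~60–120 ms) topographies. Prototype maps are
   extracted from global-field-power (GFP) peaks with a polarity-invariant
   modified K-means, the number of states K is chosen by the
   cross-validation criterion `CV = σ²((C−1)/(C−K−1))²`, and epochs around
   task starts and error events ("needle drop", "incorrect needle
   insertion") are *backfitted* by global map dissimilarity to yield
   occurrence, duration, coverage and transition statistics per group
   (expert vs novice).
2. **fNIRS–EEG fusion** — cortical oxyhemoglobin (HbO) is reconstructed
   from EEG band power (1–40 Hz) via temporally embedded, ridge-regularized
   canonical correlation analysis (tCCA); the selected canonical variates
   enter a per-channel GLM together with short-separation fNIRS channels
   (systemic nuisance) and a 3rd-order polynomial drift basis.

Raw recordings of this kind are typically restricted, so the package
includes a first-class synthetic cohort generator (`msfusion.simulate`)
producing ground-truthed EEG (BrainVision), fNIRS (SNIRF) and event
tables for a two-group cohort (13 novices + 9 experts by default), with
known prototypes, state sequences, hemodynamic coupling and systemic
physiology. Every pipeline stage is validated by parameter recovery
against this generator; see `docs/methods.md` for the model, the
defaults and their rationale, and known limitations.

Intended users: researchers in multimodal neuroimaging who want a tested,
scriptable reimplementation of this analysis style, or a simulation
harness to probe its failure modes.

## Worked example

Run the whole pipeline on a synthetic cohort from the command line:

```bash
msfusion run-all --seed 21 --out runs/demo
```

or drive the stages from Python:

```python
import numpy as np
from msfusion.config import SimConfig
from msfusion import simulate as sim, eeg, microstates as ms
from msfusion.io import template_positions

cfg = SimConfig(trial_duration_s=60, n_trials=2, rest_duration_s=10)
protos = sim.gen_prototypes(6, 32, np.random.default_rng(0),
                            positions=template_positions(32))
peaks = []
for subject in range(2):
    truth = sim.gen_state_sequence(cfg, subject, prototypes=protos)
    rec = sim.gen_eeg(truth, cfg, 100 + subject)
    clean, report = eeg.preprocess_eeg(rec)
    gfp = ms.compute_gfp(clean)
    peaks += ms.find_gfp_peaks(gfp, clean.data, seed=subject)
model, table = ms.select_k(peaks, k_range=(2, 8), restarts=30, seed=0)
print(table.round(3)[["k", "gev", "cv"]].to_string(index=False))
print("selected K =", model.k)
```

which prints (seed-exact):

```
 k   gev    cv
 2 0.483 8.941
 3 0.593 7.557
 4 0.679 6.408
 5 0.745 5.479
 6 0.794 4.803
 7 0.800 5.040
 8 0.807 5.311
selected K = 6
```

GEV climbs monotonically with K while the CV criterion bottoms out at
the generating K = 6: the six-state model explains ~79% of the
GFP-weighted topographic variance, and adding a seventh state buys
almost nothing against the CV penalty.

Each run directory contains the cohort (`cohort/`), preprocessed arrays
and per-subject cleaning reports (`prep/`), the microstate model and
(K, GEV, CV) table (`model/`), per-group microstate statistics and
transition matrices (`backfit/`), GLM fit tables and reconstructed HbO
responses (`fusion/`), group statistics (`stats/`) and a checksum
manifest (`run_manifest.json`) — re-running with the same seed
reproduces identical checksums.

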