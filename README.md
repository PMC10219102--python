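# fluxkin

Kinetic analysis of flow-cytometric Ca²⁺-flux measurements in human B-cell
subsets: from raw FCS event streams through hierarchical gating,
baseline-standardized median-fluorescence kinetic traces, double-logistic
curve fitting with nine descriptors, agonist-titration EC50 extraction and
nonparametric group statistics. A bundled synthetic-data generator emulates
the whole acquisition design, so every stage is testable end to end without
instrument data.

## The problem

Ligating the B-cell receptor (BCR) triggers a stereotyped cytoplasmic Ca²⁺
transient — a fast rise from intracellular store release, a peak, and a
decay to a sustained plateau maintained by store-operated Ca²⁺ entry
(SOCE). The shape of that transient differs between B-cell subsets (naive,
non-switched memory, switched memory, double-negative, antibody-secreting
cells) and between activating agents (anti-IgG/IgM/IgG+M, CpG, ionomycin),
and carries information about signaling competence that a single endpoint
cannot.

With a single-wavelength indicator such as Fluo-4 AM, the protocol is: record
~60 s of resting signal, remove the tube, add the activating agent, note the
elapsed gap, and record 720 s of activation. `fluxkin` appends the two
recordings on one time axis using the measured gap, standardizes the curve to
end at 780 s, gates events into subsets against FMO (fluorescence-minus-one)
controls, bins each subset's Fluo-4 signal into per-bin **medians**, and
divides by the resting fluorescence so every curve starts at 1.

## The model

Most activation curves follow a double-logistic course

```
f(t) = S + H1 / (1 + exp(-k1 (t - m1))) - H2 / (1 + exp(-k2 (t - m2)))
```

— a rising logistic (amplitude `H1`, rate `k1` s⁻¹, midpoint `m1` s) minus a
falling one. The fit (weighted nonlinear least squares, weights ∝ bin event
counts; constant and single-logistic nested alternatives selected by AICc
when `model="auto"`) is reduced to nine descriptors:

| descriptor | definition |
|---|---|
| Start | limit of `f` at −∞ (= `S`; 1 on a standardized trace) |
| Max | maximum of `f` on the observation window `[t_act, 780]` |
| Ending | limit of `f` at +∞ (= `S + H1 − H2`; the SOCE plateau) |
| T to Max | time from activation to the maximum (s) |
| T to 1st 50% | ascending crossing of `(Start+Max)/2` (s) |
| T from 50% to Max | difference of the two above (s) |
| Slope at 1st 50% | `f′` at the ascending crossing (int/s, positive) |
| T from Max to 2nd 50% | descending crossing of `(Max+Ending)/2` (s) |
| Slope at 2nd 50% | `f′` there (int/s, negative) |
| AUC | closed-form `∫ (f − S) dt` over the window (int·s) |

Titration series are summarized by the hyperbolic stimulation model
`Y = Bottom + X·(Top − Bottom)/(EC50 + X)` with per-curve R². Group
comparisons use Shapiro–Wilk screening, Wilcoxon signed-rank / Friedman +
Benjamini–Hochberg for matched designs, Kruskal–Wallis + Dunn + BH for
independent ones, and two-way ANOVA + Tukey for normal data.

## Worked example

```python
import numpy as np
from fluxkin import (default_spec, assemble_recording, bin_median_trace,
                     normalize_trace, fit_kinetic, derive_descriptors)
from fluxkin.pipeline import fmo_thresholds_for_sample, analyze_recording, RunConfig
from pathlib import Path

spec = default_spec(event_rate=300.0, seed=1)       # 5 B subsets + non-B
rec, labels = assemble_recording(spec, "IgG+M")     # 60 s + 720 s appended
thr = fmo_thresholds_for_sample(spec)               # FMO positivity gates
res = analyze_recording(rec, thr, config=RunConfig(out_dir=Path(".")))
d = res.descriptors["Sw"]                           # switched memory B cells
print(f"Max={d.max:.2f}  Ending={d.ending:.2f}  T_to_50={d.t_to_50:.0f} s")
```

prints

```
Max=2.43  Ending=1.71  T_to_50=45 s
```

i.e. after anti-IgG+M stimulation the switched-memory Ca²⁺ signal reaches
its first half-maximum 45 s into the response, peaks at 2.43× the resting
level, and settles on a plateau 1.71× baseline — matching the generator's
truth for that subset (peak 2.43, plateau 1.70). The same pipeline is
available from the shell:

```
fluxkin demo --seed 1 --out demo_out        # simulate → gate → fit → stats
fluxkin simulate --agent ionomycin --out sim # FCS pairs + FMOs + truth labels
fluxkin fit --baseline b.fcs --activation a.fcs --gap 8.5
fluxkin doseresponse --input titration.csv
```

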