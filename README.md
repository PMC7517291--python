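# afmse — multiscale entropy analysis of atrial fibrillatory waves

`afmse` predicts early recurrence of persistent atrial fibrillation (AF)
after electrical cardioversion from a single-lead surface ECG. During
AF, the P-waves of the ECG are replaced by fibrillatory (f-) waves whose
rate and disorganization reflect the proarrhythmic state of the atria.
The package implements the complete analysis chain:

1. **Preprocessing** — zero-phase removal of baseline wander (0.8 Hz
   Butterworth estimate subtracted), powerline interference (50/60 Hz
   notch, 4 Hz bandwidth) and high-frequency noise (70 Hz low-pass).
2. **f-wave extraction** — R-peak detection, ectopic labeling by
   template matching, average-beat QRST cancellation over windows of
   min(470 ms, 90% of the median RR), and a 3 Hz high-pass.
3. **Classic predictors** — f-wave amplitude FWA (RMS, mV), normalized
   amplitude nFWA, dominant frequency DF (screened Welch periodogram,
   argmax in 3–12 Hz), and Sample Entropy of the fundamental component
   ff(n) (Chebyshev-II band-pass at DF ± 2.5 Hz):

   SE(x, N, m, r) = −ln [ A^m(r) / B^m(r) ],

   with m = 2, r = 0.2·SD(ff), Chebyshev distance, strict matching and
   self-matches excluded.
4. **Multiscale entropy** — SE across coarse-graining scales τ = 1…40:
   plain block means (MSE), all-offset averaging (CMSE), and refined
   graining with anti-alias filtering and per-scale tolerance (RMSE);
   each profile summarized by region areas (ALS/AMS/AHS) and
   least-squares slopes (SLS/SMS/SHS) over τ = 1–10 / 11–20 / 21–40.
5. **Evaluation** — per-predictor group comparison (KS-routed t-test or
   Wilcoxon rank-sum), AROC by rank/pair counting, and the
   Youden-optimal Se/Sp operating point, with "relapsing to AF" as the
   positive class.

Because the clinical recordings behind this kind of analysis are not
public, the package ships a first-class **synthetic cohort generator**:
sawtooth-harmonic atrial activity with AM/FM and phase-jitter
disorganization, Gaussian-lobe QRST trains at irregular RR intervals
with optional ectopics, and realistic noise. Two archetypes ("maintaining
sinus rhythm" vs. "relapsing to AF") differ in DF center, jitter and
amplitude, so every stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from afmse import (
    CohortConfig, PipelineConfig, run_pipeline,
)

cohort = CohortConfig(n_sr=31, n_relapse=39, duration=10.0, fs=1024.0,
                      master_seed=2001)
config = PipelineConfig(n_segments=1, methods=("RMSE",))
result = run_pipeline(config, cohort)

ev = result.evaluation.set_index("predictor")
print(ev.loc[["DF", "nFWA", "SE", "RMSE_SHS"],
             ["median_pos", "median_neg", "p_value", "AROC", "Se", "Sp"]])
```

Output:

```
           median_pos  median_neg       p_value      AROC        Se        Sp
predictor
DF           5.666667    4.833333  2.309467e-09  0.889992  0.692308  1.000000
nFWA         0.050265    0.070304  7.074830e-31  0.996691  0.948718  1.000000
SE           0.110809    0.095874  1.987330e-10  0.924731  0.897436  0.838710
RMSE_SHS     0.027108    0.010397  1.142552e-15  0.930521  0.923077  0.870968
```

Reading: the relapsing group shows a higher dominant frequency
(5.67 vs 4.83 Hz), higher entropy and a steeper high-scale RMSE slope,
and a lower normalized f-wave amplitude — the directions expected from
more disorganized fibrillatory activity — and each predictor separates
the groups with the printed AROC and Youden-point sensitivity and
specificity. (Synthetic cohorts separate more cleanly than clinical
ones; the generator's archetypes control the effect size.)

The same chain is scriptable from a shell:

```bash
afmse run --seed 2001 --n-sr 31 --n-relapse 39 --duration 10 --fs 1024 \
      --n-segments 1 --methods RMSE --out results/demo
afmse synthesize --seed 7 --n-sr 2 --n-relapse 2 --duration 8 --fs 256 --out records/
afmse features --records records/ --out features.csv --n-segments 1 --methods RMSE
afmse evaluate --features features.csv --out evaluation.csv
```

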