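# cklabel

A toolkit for measuring the relative biosynthetic rate of isoprenoid
cytokinins by *in vivo* deuterium labeling and tandem mass spectrometry.

Plants grown on ~30% D₂O incorporate deuterium into newly synthesized
molecules. For a cytokinin pool, the ratio of labeled (tracer) to
unlabeled (tracee) molecules — after removing the contribution of
naturally occurring heavy isotopes — measures how much of the pool was
synthesized during the labeling window. `cklabel` provides the three
computational pieces of that workflow:

1. **Exact-mass and isotope arithmetic** — formula parsing, monoisotopic
   and nominal masses from a pinned isotope table, ppm fidelity checks,
   and natural isotopologue patterns by per-element convolution.
2. **MRM transition design** — a registry of the 11 study cytokinins
   (iP, tZ, cZ, DHZ families as free bases, ribosides and nucleotides),
   the hydroxyl-propionylation derivatization rule (+C₃H₄O, +56 Da per
   free hydroxyl), and generation of the diagnostic isotopomer ladders
   I₀–I₃ (riboside [M+H]⁺ → protonated base fragment).
3. **Tracer:tracee estimation** — conversion of measured I₀–I₃ MRM peak
   areas into a natural-abundance-corrected t/t ratio with replicate
   statistics.

## The model

For a product ion with natural satellite pattern *r* (relative to its
monoisotopic peak, r₀ = 1), molecules carrying *j* deuterium labels
contribute signal r₀, r₁, … starting at channel I_j, because both MRM
ions shift together by +j Da. Writing x_j for the amount of the j-label
class, the expected channel areas are

    I = C x,   C[i, j] = r_{i−j}  (i ≥ j; 0 otherwise)

The deconvolution solves min ‖Cx − I‖₂ subject to x ≥ 0 (non-negative
least squares; an exact forward-substitution "subtraction" estimator is
available as a cross-check), and the tracer:tracee ratio is

    t/t = (x₁ + x₂ + x₃) / x₀

computed per replicate, then aggregated as mean ± sample SD.

## Worked example

Simulate five replicate injections of propionylated
isopentenyladenosine at a true t/t of 1.68 with 5% multiplicative
noise, then fit:

```python
from cklabel import SimulationConfig, TracerTraceeModel, simulate_measurement

cfg = SimulationConfig(analyte="pro-iPR", seed=42, tt=1.68,
                       cv=0.05, n_replicates=5)
results = TracerTraceeModel(simulate_measurement(cfg)).fit()
print(results.summary())
```

```
Tracer:Tracee Deconvolution Results
===========================================
Analyte:            pro-iPR
Product ion:        C10H14N5+
Estimator:          nnls
Window:             I0..I3
Replicates:         5
Condition number:   1.2301
Mean rel. residual: 1.338e-03
-------------------------------------------
label class   mean fraction
  x0 (  tracee)     0.375668
  x1 (+1 label)     0.618471
  x2 (+2 label)     0.005861
  x3 (+3 label)     0.000000
-------------------------------------------
t/t ratio:          1.6647 +/- 0.0963
```

The fit recovers the true ratio (1.68) within the noise level: about
63% of the pool carries one label, and the condition number near 1
shows the correction matrix is numerically benign. Real measurements
enter through a peak-area CSV instead of the simulator (see below).

## Command line

```sh
cklabel mass C5H9+ --experimental 69.0703   # exact m/z 69.0704, ppm -1.4
cklabel pattern C10H14N5+ --k 3             # natural isotopologue pattern
cklabel transitions --analyte iPR --derivatized   # 504-204 ... 507-207
cklabel simulate --config sim.yaml --out areas.csv
cklabel tt --input areas.csv --out results.csv
```

`tt` consumes a CSV with columns `analyte, replicate, I0, I1, I2, I3`
and writes one row per analyte: `analyte, n, tt_mean, tt_sd, residual`.

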