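# Methods

## Scope and model

`cklabel` computes the relative biosynthetic rate of isoprenoid
cytokinins from deuterium-labeling MRM data. "Relative biosynthetic
rate" here means the measured degree of labeling of a compound pool —
the tracer:tracee ratio t/t — not an absolute flux. The package covers
the desk side of the workflow: mass arithmetic, transition design, and
signal-to-ratio conversion. Chromatography, extraction chemistry and
instrument control are out of scope.

### Mass conventions

- **Monoisotopic mass** is the sum of principal-isotope (lightest)
  atomic masses. For cations the electron mass is *not* subtracted:
  at unit and 4-d.p. precision this neutral-atom convention is what
  matches the reference values quoted for the side-chain fragments
  (C₅H₉⁺ → 69.0704; subtracting an electron would give 69.0699).
- **Nominal mass** is the sum of integer mass numbers; deuterium counts
  as 2. MRM transitions are expressed at unit resolution (triple
  quadrupole), with exact masses retained as metadata.
- **ppm fidelity** is (experimental − calculated)/calculated × 10⁶.
  When quoting fidelity against a calculated value displayed at 4 d.p.
  (the `cklabel mass --experimental` path), the calculated value is
  rounded to 4 d.p. first so the quoted ppm matches what a reader
  computes from the displayed numbers.
- **Deuterium** is its own element symbol `D` with a single isotope at
  abundance 1: a label atom, never part of natural-abundance
  statistics. The formula grammar is `(Symbol Count?)+` with optional
  whitespace and a trailing `+`; no bracketed isotope syntax.

The isotope table (masses and natural abundances for H, D, C, N, O, P)
is pinned in `src/cklabel/data/isotopes.tsv` and checksummed in the
test suite; reproducibility is preferred over live lookups. P has a
single stable isotope; O and N heavy isotopes are included even though
their contributions are small.

### Compound registry and derivatization

The registry holds the 11 study compounds: the iP, tZ, cZ families as
free base / riboside / riboside-5'-monophosphate, and DHZ as base and
riboside. Structural arithmetic is compositional: riboside = base +
C₅H₈O₄ (ribose condensation, +132 nominal), nucleotide = riboside +
HPO₃ (+80). cis/trans zeatin isomers share formulas and transitions
and are distinguished by identity only (chromatographic separation is
upstream).

Propionylation acylates free hydroxyls only (+C₃H₄O, +56 nominal
each): 3 on a riboside's sugar, plus 1 on a hydroxylated zeatin-type
side chain. This assignment is forced by the transition arithmetic
(504 = 336 + 3×56 for pro-iPR; 576 = 352 + 4×56 for pro-tZR).
Nucleotides are rejected by `propionylate`: in the workflow they are
dephosphorylated by alkaline phosphatase and measured as ribosides.
Derivatizing twice is rejected (no free hydroxyls remain).

Diagnostic transitions are defined for ribosides: precursor = [M+H]⁺
of the (propionylated) riboside, product = protonated base fragment
after neutral loss of the (propionylated) ribose. A side-chain
propionyl is retained on the product ion (276 = 220 + 56 for pro-tZR),
i.e. the fragment keeps side-chain substituents and loses sugar
substituents. The isotopomer ladder I₀..I₃ adds +j Da to both ions.
The iP-type side-chain fragment C₅H₉⁺ (m/z 69; C₅H₃D₆⁺, m/z 75 when
the two terminal methyls are deuterated) is exposed by the registry but
not part of the default ladder generation, since only the riboside
ladders carry tabulated isotopomer series.

### Isotope patterns

The natural isotopologue distribution of a formula is computed by
polynomial convolution: each atom contributes a distribution over
integer mass-number shifts (e.g. carbon: +0 with 0.9893, +1 with
0.0107), and the molecular pattern is the product distribution,
computed by exponentiation-by-squaring of per-element polynomials and
truncated at shift k (default k = 3, the monitored window;
configurable). Aggregation is by integer mass shift, matching a
unit-resolution quadrupole; isotope fine structure is not resolved.
The implementation is verified against an independent brute-force
oracle that enumerates all isotope assignments exactly (agreement to
1e-10 per channel for the fragment ions used).

### Deconvolution and t/t

With r the fragment's satellite pattern relative to monoisotopic
(r₀ = 1), the mixing model is I = Cx with C[i,j] = r_{i−j}, lower
triangular with unit diagonal. Two estimators are provided:

- `nnls` (default): min ‖Cx − I‖₂ s.t. x ≥ 0, via the deterministic
  active-set NNLS solver. Negative excess is handled by the
  constraint, never clipped post hoc.
- `subtraction`: exact forward substitution of the triangular system —
  sequentially stripping each channel of the satellites of the
  channels below. It can return negative classes under noise and
  serves as a cross-check; on noiseless data the two estimators agree
  to numerical precision, and that equivalence is tested.

t/t = (x₁ + x₂ + x₃)/x₀, computed per replicate and aggregated as
arithmetic mean ± sample SD (n−1). Replicate identity is opaque
(biological or injection replicates are treated alike). If x₀ = 0 the
labeling is flagged as saturated and no finite ratio is returned.

Two modelling approximations are documented rather than solved:

- The correction uses the **product-ion formula** only. Natural heavy
  isotopes in the neutral loss move signal out of the ladder for every
  channel alike, acting as a common scale factor that cancels in t/t;
  isotopes in the fragment are what the ladder discriminates.
- All columns of C use the unlabeled fragment's pattern. A j-labeled
  molecule has j fewer natural hydrogens, but at a natural ²H abundance
  of 1.15×10⁻⁴ the difference is far below the solver tolerance.
- Label classes beyond the window (e.g. a fully D₆-labeled side chain
  at +6) are not counted: the reported t/t is a lower bound under
  heavy labeling.

### Numerical behavior

The correction matrix is well conditioned (condition number ≈ 1.2 for
C₁₀H₁₄N₅⁺ at k = 3), so the deconvolution is numerically benign; the
condition number and relative residual are reported as diagnostics.
Strict monotonicity of t/t in the labeled channels holds wherever the
NNLS solution is interior — in particular for any measurement
consistent with the mixing model. For grossly inconsistent inputs the
non-negativity constraint can activate, and the ordering is then sharp
only to solver tolerance; the property tests therefore randomize over
model-consistent measurements, which is the physically meaningful
domain. Scale invariance of t/t is exact.

## Synthetic data generator

`SimulationConfig`/`simulate_measurement` emulate what the instrument
reports for a known ground truth: expected areas I = Cx scaled to a
total ion count (default 10⁶, a typical integrated MRM peak area for a
well-responding propionylated cytokinin), perturbed by multiplicative
Gaussian noise (CV) and/or Poisson counting noise, for n replicates
(default 5, matching the replicate depth of the comparison
experiments). A scalar t/t setpoint places all tracer mass in the
single-label class x₁ — the dominant class for a 30% D₂O feed within
a 4-channel window — and a vector split is available. Seeds are
mandatory; there is no implicit global randomness.
`simulate_timecourse` strings setpoints into a labeling series.

The generator does **not** emulate chromatographic peak shape or
integration error, matrix interferences, or the deuterium
incorporation chemistry itself (no precursor-pool model). Passing
tests therefore demonstrate estimator correctness on the stated noise
models, not robustness to real-matrix artifacts.

Test and validation problem sizes: noiseless round trips cover all
8 riboside analyte states (4 ribosides × underivatized/derivatized);
parameter-recovery runs use published-scale setpoints (t/t ≈ 1.3–1.7)
at CV 1–10% with 5 replicates; property checks run 1000 randomized
deconvolution cases; the brute-force isotope oracle enumerates
assignments for ions up to C₁₃H₁₈N₅O₂⁺.

## Batch IO

Peak areas enter as RFC-4180 CSV (`analyte, replicate, I0..I3`,
"." decimal); vendor-format conversion is the user's concern.
Validation is exhaustive — every offending row is reported with its
line number in one error. Batch processing deconvolves analytes
independently, logs condition numbers and residuals, skips failing
analytes while continuing, and emits a deterministic, input-order-
independent results table.

## Known limitations

- Only [M+H]⁺ adducts, positive mode, charge ≤ +1.
- Glucosides and aromatic cytokinins are not in the registry.
- The t/t value is relative labeling, not an absolute synthesis flux;
  precursor-pool enrichment (the D₂O fraction) is not modelled.
- The window default k = 3 truncates heavier label classes (see the
  lower-bound caveat above).
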