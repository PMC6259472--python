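"""Tracer:tracee ratio estimation from MRM isotopomer peak areas.

The measured channel areas I_0..I_k of an isotopomer ladder mix two
things: genuine deuterium labeling (the tracer classes with 1, 2, 3
labels) and the natural heavy-isotope satellites (13C, 2H, 15N, 17/18O)
of every species in the mix. Writing x_j for the amount of molecules
carrying exactly j deuterium labels inside the monitored window, the
expected signal is

    I = C x,        C[i, j] = r_{i-j}  (i >= j, else 0),

where r is the natural satellite pattern of the *product-ion* formula
relative to its monoisotopic peak (r_0 = 1): each labeled class drags
the same natural pattern along, shifted up by its label count. The
deconvolution solves this linear system with a non-negativity
constraint (NNLS), and the tracer:tracee ratio is

    t/t = (x_1 + x_2 + x_3) / x_0 .

An alternative "subtraction" estimator — exact forward substitution of
the triangular system, equivalent to sequentially stripping each
channel of the natural satellites of the channels below it — is
provided as a cross-check; on noiseless data the two agree exactly.

The correction uses the product-ion formula, not the precursor: both
MRM ions shift together by +j, so the ladder discriminates isotopes
residing in the fragment, while natural isotopes in the neutral loss
divert signal out of every channel alike and cancel in the ratio.

The model/results pair (:class:`TracerTraceeModel`,
:class:`TracerTraceeResults`) wraps these primitives with replicate
handling, diagnostics and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .elements import ChemicalFormula
from .isotope_pattern import natural_pattern, relative_to_monoisotopic

__all__ = [
    "IsotopomerMeasurement",
    "EnrichmentResult",
    "SaturatedLabelingError",
    "correction_matrix",
    "deconvolve",
    "tracer_tracee_ratio",
    "replicate_stats",
    "TracerTraceeModel",
    "TracerTraceeResults",
]


class SaturatedLabelingError(ValueError):
    """No unlabeled (tracee) signal: the t/t ratio is not finite."""


@dataclass(frozen=True)
class IsotopomerMeasurement:
    """Peak areas of one isotopomer ladder for one replicate.

    ``areas[j]`` is the area of channel I_j (arbitrary units, >= 0).
    ``product_formula`` is the product-ion composition used to build
    the natural-abundance correction.
    """

    analyte: str
    replicate: str
    areas: tuple[float, ...]
    product_formula: ChemicalFormula

    def __post_init__(self):
        areas = tuple(float(a) for a in self.areas)
        if any(a < 0 for a in areas):
            raise ValueError(f"negative peak area in {areas!r}")
        if not any(areas):
            raise ValueError("all-zero measurement vector")
        object.__setattr__(self, "areas", areas)

    @property
    def k(self) -> int:
        return len(self.areas) - 1


@dataclass(frozen=True)
class EnrichmentResult:
    """Deconvolved label-class fractions and t/t for one analyte."""

    analyte: str
    fractions: np.ndarray          # mean x_0..x_k over replicates, normalized
    tt: float                      # mean t/t
    tt_per_replicate: tuple[float, ...]
    tt_sd: float | None            # sample SD (n-1), None for n < 2
    n_replicates: int
    residual: float                # mean NNLS residual norm, relative


def correction_matrix(
    fragment: ChemicalFormula, k: int = 3
) -> np.ndarray:
    """Natural-abundance correction matrix for a product-ion formula.

    Lower-triangular (k+1) x (k+1); column j is the natural satellite
    pattern of the fragment, relative to its monoisotopic peak, shifted
    up by j label mass units: C[i, j] = r_{i-j}. All columns share the
    unlabeled fragment's pattern (the label substitutes H atoms whose
    natural-abundance contribution is negligible at these counts) and
    the same normalization, diagonal = 1.
    """
    if k < 0:
        raise ValueError(f"window must be >= 0, got {k}")
    r = relative_to_monoisotopic(natural_pattern(fragment, k=k))
    C = np.zeros((k + 1, k + 1))
    for j in range(k + 1):
        C[j:, j] = r[: k + 1 - j]
    return C


def _forward_substitution(C: np.ndarray, I: np.ndarray) -> np.ndarray:
    # sequential satellite stripping: x_j = I_j - sum_{m<j} x_m r_{j-m}
    x = np.zeros_like(I)
    for j in range(len(I)):
        x[j] = I[j] - C[j, :j] @ x[:j]
    return x


def deconvolve(
    m: IsotopomerMeasurement,
    k: int | None = None,
    estimator: str = "nnls",
) -> tuple[np.ndarray, float]:
    """Recover label-class amounts x from measured channel areas.

    ``estimator``: ``"nnls"`` solves min ||Cx - I|| subject to x >= 0
    (deterministic active-set solve); ``"subtraction"`` performs exact
    forward substitution of the triangular system, which can yield
    negative classes under noise and exists as a cross-check.

    Returns ``(x, residual)`` with the residual as ||Cx - I|| / ||I||.
    """
    I = np.asarray(m.areas, dtype=float)
    if k is None:
        k = m.k
    if k + 1 != len(I):
        raise ValueError(f"window {k} does not match {len(I)} channels")
    C = correction_matrix(m.product_formula, k=k)
    if estimator == "nnls":
        x, rnorm = scipy.optimize.nnls(C, I)
    elif estimator == "subtraction":
        x = _forward_substitution(C, I)
        rnorm = 0.0  # exact solve of the triangular system
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return x, float(rnorm / np.linalg.norm(I))


def tracer_tracee_ratio(x: np.ndarray) -> float:
    """t/t = (sum of labeled classes) / unlabeled class.

    Counts only label classes inside the monitored window (a lower
    bound when heavier isotopologues, e.g. fully D6-labeled side
    chains, fall outside the ladder).
    """
    x = np.asarray(x, dtype=float)
    if x[0] <= 0:
        raise SaturatedLabelingError(
            "no tracee (unlabeled) signal recovered; t/t is not finite"
        )
    return float(x[1:].sum() / x[0])


def replicate_stats(tt_values) -> tuple[float, float | None]:
    """Arithmetic mean and sample SD (n-1 denominator) of per-replicate
    t/t values; SD is None for fewer than two replicates."""
    tt = np.asarray(list(tt_values), dtype=float)
    if tt.size == 0:
        raise ValueError("no replicate values")
    mean = float(tt.mean())
    sd = float(tt.std(ddof=1)) if tt.size >= 2 else None
    return mean, sd


class TracerTraceeModel:
    """Linear isotopomer-mixing model for one analyte's replicate set.

    Parameters
    ----------
    measurements : sequence of IsotopomerMeasurement
        All replicates of a single analyte; window lengths and product
        formulas must agree.
    k : int, optional
        Window size; defaults to the measurements' channel count - 1.

    ``fit()`` deconvolves each replicate independently and aggregates
    t/t as mean and sample SD across replicates.
    """

    def __init__(self, measurements, k: int | None = None):
        measurements = list(measurements)
        if not measurements:
            raise ValueError("at least one measurement required")
        analytes = {m.analyte for m in measurements}
        if len(analytes) != 1:
            raise ValueError(f"one analyte per model, got {sorted(analytes)}")
        formulas = {m.product_formula for m in measurements}
        if len(formulas) != 1:
            raise ValueError("replicates disagree on product-ion formula")
        widths = {m.k for m in measurements}
        if len(widths) != 1:
            raise ValueError("replicates disagree on window length")
        self.measurements = measurements
        self.analyte = analytes.pop()
        self.product_formula = formulas.pop()
        self.k = widths.pop() if k is None else k

    @classmethod
    def from_dataframe(cls, df, product_formula: ChemicalFormula,
                       analyte: str | None = None) -> "TracerTraceeModel":
        """Build from a tidy frame with columns analyte, replicate,
        I0..Ik (one row per replicate)."""
        channels = sorted(
            (c for c in df.columns if c.startswith("I") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        rows = [
            IsotopomerMeasurement(
                analyte=row["analyte"],
                replicate=str(row["replicate"]),
                areas=tuple(float(row[c]) for c in channels),
                product_formula=product_formula,
            )
            for _, row in df.iterrows()
        ]
        return cls(rows)

    @property
    def correction(self) -> np.ndarray:
        return correction_matrix(self.product_formula, k=self.k)

    def fit(self, estimator: str = "nnls") -> "TracerTraceeResults":
        xs, tts, residuals = [], [], []
        for m in self.measurements:
            x, res = deconvolve(m, k=self.k, estimator=estimator)
            tts.append(tracer_tracee_ratio(x))
            xs.append(x / x.sum() if x.sum() > 0 else x)
            residuals.append(res)
        mean, sd = replicate_stats(tts)
        return TracerTraceeResults(
            model=self,
            estimator=estimator,
            fractions=np.mean(xs, axis=0),
            tt_per_replicate=tuple(tts),
            tt=mean,
            tt_sd=sd,
            residuals=tuple(residuals),
        )


@dataclass(frozen=True)
class TracerTraceeResults:
    """Fit output: label-class fractions, t/t with replicate SD, and
    deconvolution diagnostics."""

    model: TracerTraceeModel
    estimator: str
    fractions: np.ndarray
    tt_per_replicate: tuple[float, ...]
    tt: float
    tt_sd: float | None
    residuals: tuple[float, ...]
    condition_number: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "condition_number",
            float(np.linalg.cond(self.model.correction)),
        )

    @property
    def n_replicates(self) -> int:
        return len(self.tt_per_replicate)

    def as_record(self) -> EnrichmentResult:
        return EnrichmentResult(
            analyte=self.model.analyte,
            fractions=self.fractions,
            tt=self.tt,
            tt_per_replicate=self.tt_per_replicate,
            tt_sd=self.tt_sd,
            n_replicates=self.n_replicates,
            residual=float(np.mean(self.residuals)),
        )

    def summary(self) -> str:
        lines = [
            "Tracer:Tracee Deconvolution Results",
            "=" * 43,
            f"Analyte:            {self.model.analyte}",
            f"Product ion:        {self.model.product_formula}",
            f"Estimator:          {self.estimator}",
            f"Window:             I0..I{self.model.k}",
            f"Replicates:         {self.n_replicates}",
            f"Condition number:   {self.condition_number:.4f}",
            f"Mean rel. residual: {float(np.mean(self.residuals)):.3e}",
            "-" * 43,
            "label class   mean fraction",
        ]
        for j, x in enumerate(self.fractions):
            tag = "tracee" if j == 0 else f"+{j} label"
            lines.append(f"  x{j} ({tag:>8s})   {x:10.6f}")
        lines.append("-" * 43)
        sd = f" +/- {self.tt_sd:.4f}" if self.tt_sd is not None else ""
        lines.append(f"t/t ratio:          {self.tt:.4f}{sd}")
        return "\n".join(lines)
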