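"""Synthetic isotopomer measurements with known ground truth.

Emulates what the triple quadrupole reports for a labeled analyte: the
true label-class amounts x are pushed through the natural-abundance
mixing model (I = C x), scaled to a realistic total ion count, and
perturbed with counting (Poisson) and/or multiplicative (Gaussian CV)
noise. Ground truth is known exactly, so estimator bias and variance
can be measured — which real extracts never allow.

What this does NOT emulate: chromatographic peak shape and integration
error, matrix interferences and in-source chemistry, or the deuterium
incorporation chemistry itself (label classes are set directly, not
grown from a precursor-pool model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compounds import diagnostic_transitions, get_compound
from .elements import ChemicalFormula
from .enrichment import IsotopomerMeasurement, correction_matrix

__all__ = ["SimulationConfig", "simulate_measurement", "simulate_timecourse"]

#: Default total ion count per ladder; typical integrated MRM peak-area
#: magnitude for a well-responding propionylated cytokinin.
DEFAULT_TOTAL_SIGNAL = 1e6


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise model for one simulated replicate set.

    Either give the tracer fractions per label class directly
    (``tracer_fractions``, relative to tracee = 1) or a scalar ``tt``
    that is placed entirely in the single-label class x_1 — the
    dominant class for a 30% D2O feed within a 4-channel window.

    ``cv`` is multiplicative Gaussian noise (coefficient of variation);
    ``poisson`` adds shot noise on counts. A seed is mandatory: no
    implicit global randomness.
    """

    analyte: str
    seed: int
    tt: float | None = None
    tracer_fractions: tuple[float, ...] | None = None
    total_signal: float = DEFAULT_TOTAL_SIGNAL
    cv: float = 0.0
    poisson: bool = False
    n_replicates: int = 5
    k: int = 3

    def true_x(self) -> np.ndarray:
        """Ground-truth class vector (x_0 = 1 tracee unit)."""
        x = np.zeros(self.k + 1)
        x[0] = 1.0
        if self.tracer_fractions is not None:
            frac = np.asarray(self.tracer_fractions, dtype=float)
            if frac.size != self.k or (frac < 0).any():
                raise ValueError(
                    f"need {self.k} non-negative tracer fractions, got {frac!r}"
                )
            x[1:] = frac
        elif self.tt is not None:
            if self.tt < 0:
                raise ValueError(f"t/t must be >= 0, got {self.tt}")
            x[1] = self.tt
        else:
            raise ValueError("give either tt or tracer_fractions")
        return x

    def __post_init__(self):
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        self.true_x()  # validate eagerly


def _product_formula(analyte: str) -> ChemicalFormula:
    derivatized = analyte.startswith("pro-")
    base = get_compound(analyte[4:] if derivatized else analyte)
    return diagnostic_transitions(base, derivatized=derivatized).product_formula


def simulate_measurement(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[IsotopomerMeasurement]:
    """Generate one ladder of peak areas per replicate.

    Expected signal is C x scaled so the channel sum equals
    ``total_signal``; noise is applied per channel. Deterministic under
    a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fragment = _product_formula(cfg.analyte)
    C = correction_matrix(fragment, k=cfg.k)
    expected = C @ cfg.true_x()
    expected *= cfg.total_signal / expected.sum()

    out = []
    for rep in range(1, cfg.n_replicates + 1):
        areas = expected.copy()
        if cfg.cv > 0:
            areas = areas * (1.0 + cfg.cv * rng.standard_normal(areas.size))
        if cfg.poisson:
            areas = rng.poisson(np.clip(areas, 0, None)).astype(float)
        areas = np.clip(areas, 0, None)
        out.append(
            IsotopomerMeasurement(
                analyte=cfg.analyte,
                replicate=f"r{rep}",
                areas=tuple(areas),
                product_formula=fragment,
            )
        )
    return out


def simulate_timecourse(
    setpoints, base_config: SimulationConfig
) -> list[tuple[float, list[IsotopomerMeasurement]]]:
    """Simulate a labeling timecourse from (time, t/t) setpoints.

    Each time point reuses the base config with its t/t replaced;
    replicate draws advance one shared generator so points are
    independent but the whole course is reproducible from one seed.
    """
    from dataclasses import replace

    rng = np.random.default_rng(base_config.seed)
    course = []
    for time, tt in setpoints:
        if tt < 0:
            raise ValueError(f"setpoint t/t must be >= 0, got {tt} at t={time}")
        cfg = replace(base_config, tt=tt, tracer_fractions=None)
        course.append((time, simulate_measurement(cfg, rng=rng)))
    return course
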