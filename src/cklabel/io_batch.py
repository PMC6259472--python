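"""CSV ingestion, batch deconvolution and results export.

The data surface is integrated MRM peak areas, not raw spectra: a
plain CSV (RFC-4180, "." decimal) with columns
``analyte, replicate, I0, I1, I2, I3``, one row per replicate ladder.
Validation is strict and exhaustive — a bad file is rejected with
*every* offending row named by line number, not just the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import IsotopomerMeasurement, TracerTraceeModel
from .synthetic import _product_formula

__all__ = [
    "AreaTable",
    "AreaTableError",
    "read_area_csv",
    "write_area_csv",
    "run_batch",
    "write_results_csv",
]

logger = logging.getLogger("cklabel")

CHANNELS = ["I0", "I1", "I2", "I3"]
REQUIRED_COLUMNS = ["analyte", "replicate", *CHANNELS]


class AreaTableError(ValueError):
    """Raised with the full list of validation failures for a file."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid peak-area table:\n  " + "\n  ".join(self.problems)
        )


@dataclass(frozen=True)
class AreaTable:
    """Validated peak-area rows with their source line numbers."""

    frame: pd.DataFrame  # columns: line, analyte, replicate, I0..I3

    def __len__(self) -> int:
        return len(self.frame)

    def measurements(self) -> dict[str, list[IsotopomerMeasurement]]:
        """Group rows into per-analyte measurement lists."""
        grouped: dict[str, list[IsotopomerMeasurement]] = {}
        for analyte, rows in self.frame.groupby("analyte", sort=True):
            fragment = _product_formula(analyte)
            grouped[analyte] = [
                IsotopomerMeasurement(
                    analyte=analyte,
                    replicate=str(row["replicate"]),
                    areas=tuple(float(row[c]) for c in CHANNELS),
                    product_formula=fragment,
                )
                for _, row in rows.sort_values("replicate").iterrows()
            ]
        return grouped


def _validate(df: pd.DataFrame) -> AreaTable:
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AreaTableError([f"missing column(s): {', '.join(missing)}"])

    from .compounds import get_compound  # late import to avoid cycle

    for _, row in df.iterrows():
        line = int(row["line"])
        analyte = str(row["analyte"])
        try:
            get_compound(analyte)
        except KeyError:
            problems.append(f"line {line}: unknown analyte {analyte!r}")
        for c in CHANNELS:
            value = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.isna(value):
                problems.append(f"line {line}: non-numeric {c}={row[c]!r}")
            elif value < 0:
                problems.append(f"line {line}: negative area {c}={value}")
    dupes = df.duplicated(subset=["analyte", "replicate"], keep=False)
    for _, row in df[dupes].iterrows():
        problems.append(
            f"line {int(row['line'])}: duplicate (analyte, replicate) "
            f"({row['analyte']}, {row['replicate']})"
        )
    if problems:
        raise AreaTableError(problems)
    out = df.copy()
    out[CHANNELS] = out[CHANNELS].astype(float)
    return AreaTable(frame=out)


def read_area_csv(path) -> AreaTable:
    """Read and validate a peak-area CSV.

    Line numbers in error messages count the header as line 1.
    """
    df = pd.read_csv(path, dtype=str)
    df.insert(0, "line", df.index + 2)  # header occupies line 1
    return _validate(df)


def write_area_csv(measurements, path) -> None:
    """Write measurements in the same CSV dialect ``read_area_csv`` reads."""
    rows = [
        {
            "analyte": m.analyte,
            "replicate": m.replicate,
            **{f"I{j}": a for j, a in enumerate(m.areas)},
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def run_batch(
    table: AreaTable, estimator: str = "nnls"
) -> tuple[pd.DataFrame, list[str]]:
    """Deconvolve every analyte in the table; skip failures, keep going.

    Returns ``(results, failed_analytes)``. Results hold one row per
    analyte, sorted by analyte name (independent of input row order):
    analyte, n, tt_mean, tt_sd, residual. Correction condition numbers,
    residuals and any per-analyte failures go to the ``cklabel`` logger.
    """
    if not len(table):
        logger.warning("empty peak-area table: no analytes to process")
    rows = []
    failures: list[str] = []
    for analyte, group in table.frame.groupby("analyte", sort=True):
        try:
            fragment = _product_formula(analyte)
            measurements = [
                IsotopomerMeasurement(
                    analyte=analyte,
                    replicate=str(row["replicate"]),
                    areas=tuple(float(row[c]) for c in CHANNELS),
                    product_formula=fragment,
                )
                for _, row in group.sort_values("replicate").iterrows()
            ]
            results = TracerTraceeModel(measurements).fit(estimator=estimator)
            logger.info(
                "%s: n=%d cond=%.4f residual=%.3e t/t=%.4f",
                analyte, results.n_replicates, results.condition_number,
                float(np.mean(results.residuals)), results.tt,
            )
            rows.append(
                {
                    "analyte": analyte,
                    "n": results.n_replicates,
                    "tt_mean": results.tt,
                    "tt_sd": results.tt_sd,
                    "residual": float(np.mean(results.residuals)),
                }
            )
        except Exception as exc:  # per-analyte failure: report and continue
            logger.error("%s: skipped (%s)", analyte, exc)
            failures.append(analyte)
    results = pd.DataFrame(
        rows, columns=["analyte", "n", "tt_mean", "tt_sd", "residual"]
    )
    return results, failures


def write_results_csv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False, float_format="%.6g")
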