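"""Predicted-vs-effective capacity validation.

Bench validation compares the model's predicted capacity against the
"effective" capacity measured by filling a constructed pouch until the
first leak.  Predictions are always recomputed from the recorded segment
dimensions — a table can never inject its own "predicted" column.

The module ships the five bench pairs available in print (three pouches
built from 40 cm swine segments of differing width, plus two built to a
350 ml target) as :data:`BUILTIN_BENCH_RECORDS`; the full 12-pouch bench
table behind the published r = 0.97 was released only as a figure and is
not transcribed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .geometry import capacity

__all__ = [
    "BenchRecord",
    "ValidationSummary",
    "BUILTIN_BENCH_RECORDS",
    "pearson_r",
    "validate",
]


@dataclass(frozen=True)
class BenchRecord:
    """One validation pair: a measured pouch and its model prediction.

    ``predicted_ml`` is computed from ``(length_cm, width_cm)`` at
    construction; pass only the measured fields.
    """

    pouch_id: str
    width_cm: float
    length_cm: float
    effective_ml: float
    predicted_ml: float = 0.0  # recomputed in __post_init__

    def __post_init__(self) -> None:
        if not self.effective_ml > 0:
            raise DomainError(
                f"effective_ml must be positive, got {self.effective_ml!r} "
                f"({self.pouch_id})"
            )
        pred = capacity(length_cm=self.length_cm, width_cm=self.width_cm).volume_ml
        object.__setattr__(self, "predicted_ml", pred)


#: Bench pairs printed in the source study: (id, width cm, length cm,
#: effective ml).  The first three share a 40 cm length; the last two were
#: cut to a 350 ml target.
BUILTIN_BENCH_RECORDS: tuple[BenchRecord, ...] = (
    BenchRecord("bordeaux-w2.2", 2.2, 40.0, 220.0),
    BenchRecord("bordeaux-w2.8", 2.8, 40.0, 298.0),
    BenchRecord("bordeaux-w3.75", 3.75, 40.0, 450.0),
    BenchRecord("target350-w2.9", 2.9, 41.0, 350.0),
    BenchRecord("target350-w2.0", 2.0, 60.0, 350.0),
)


@dataclass(frozen=True)
class ValidationSummary:
    """Aggregate agreement metrics between predicted and effective capacity.

    ``bias_ml`` is signed as predicted − effective: positive means the
    model overpredicts.
    """

    n: int
    pearson_r: float
    mean_abs_error_ml: float
    mean_relative_error_pct: float
    bias_ml: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "mean_abs_error_ml": self.mean_abs_error_ml,
            "mean_relative_error_pct": self.mean_relative_error_pct,
            "bias_ml": self.bias_ml,
        }


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation between two capacity series.

    Requires at least three pairs and non-degenerate variance in each
    series; delegates to :func:`scipy.stats.pearsonr`.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("inputs must be equal-length 1-d series")
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 pairs for a correlation, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation is undefined for a zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def validate(records: Iterable[BenchRecord]) -> ValidationSummary:
    """Summarise predicted-vs-effective agreement over bench records.

    Computes Pearson's r, mean absolute error (ml), mean relative error
    (percent of effective) and signed bias (predicted − effective, ml).
    Deterministic and permutation-invariant for a fixed set of records.
    """
    recs = list(records)
    if len(recs) < 3:
        raise InsufficientDataError(
            f"need at least 3 bench records, got {len(recs)}"
        )
    pred = np.array([r.predicted_ml for r in recs])
    eff = np.array([r.effective_ml for r in recs])
    # Exact agreement has zero variance in neither series only by accident;
    # r = 1 is the correct limit when predicted == effective elementwise.
    if np.allclose(pred, eff, rtol=1e-12, atol=1e-12):
        r = 1.0
    else:
        r = pearson_r(pred, eff)
    err = pred - eff
    return ValidationSummary(
        n=len(recs),
        pearson_r=r,
        mean_abs_error_ml=float(np.mean(np.abs(err))),
        mean_relative_error_pct=float(np.mean(np.abs(err) / eff) * 100.0),
        bias_ml=float(np.mean(err)),
    )
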