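"""Annual transition probabilities from trial-style cumulative curves.

Published trials report cumulative incidence of ipsilateral breast tumor
recurrence (IBTR) and overall survival as curves over follow-up years.
A discrete-cycle cohort model needs annual conditional probabilities.
The conversion conditions on the at-risk set at the start of each year:

* incidence curve C:  p[t] = (C[t] - C[t-1]) / (1 - C[t-1])
* survival curve S:   p[t] = 1 - S[t] / S[t-1]

Both are cause-specific reads of the curve, without a competing-risk
correction.  ``cumulative_from_annual`` is the exact inverse and is used
for round-trip testing and synthetic-curve generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INCIDENCE = "incidence"
SURVIVAL = "survival"

__all__ = [
    "CumulativeCurve",
    "annual_probs_from_cumulative_incidence",
    "annual_probs_from_survival",
    "cumulative_from_annual",
    "read_curve_csv",
    "write_curve_csv",
]


class CurveError(ValueError):
    """A curve violates its monotonicity/range invariants."""


@dataclass(frozen=True)
class CumulativeCurve:
    """A cumulative curve over years 0..T.

    ``kind`` is ``"incidence"`` (starts at 0, non-decreasing) or
    ``"survival"`` (starts at 1, non-increasing); values are fractions.
    """

    kind: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if self.kind not in (INCIDENCE, SURVIVAL):
            raise CurveError(f"kind must be '{INCIDENCE}' or '{SURVIVAL}', got {self.kind!r}")
        if len(vals) < 2:
            raise CurveError("curve needs at least years 0 and 1")
        arr = np.asarray(vals)
        if np.any(arr < 0) or np.any(arr > 1):
            raise CurveError("curve values must lie in [0, 1]")
        if self.kind == INCIDENCE:
            if vals[0] != 0.0:
                raise CurveError("incidence curve must start at 0")
            if np.any(np.diff(arr) < 0):
                raise CurveError("incidence curve must be non-decreasing")
        else:
            if vals[0] != 1.0:
                raise CurveError("survival curve must start at 1")
            if np.any(np.diff(arr) > 0):
                raise CurveError("survival curve must be non-increasing")

    @property
    def horizon(self) -> int:
        return len(self.values) - 1


def annual_probs_from_cumulative_incidence(curve: CumulativeCurve) -> np.ndarray:
    """Annual conditional event probabilities from a cumulative-incidence curve."""
    if curve.kind != INCIDENCE:
        raise CurveError(f"expected an incidence curve, got {curve.kind!r}")
    c = np.asarray(curve.values)
    at_risk = 1.0 - c[:-1]
    if np.any((at_risk == 0) & (np.diff(c) > 0)):
        raise CurveError("cumulative incidence reaches 1 and then increases")
    with np.errstate(invalid="ignore"):
        p = np.where(at_risk > 0, np.diff(c) / np.where(at_risk > 0, at_risk, 1.0), 0.0)
    return p


def annual_probs_from_survival(curve: CumulativeCurve) -> np.ndarray:
    """Annual conditional death probabilities from a survival curve."""
    if curve.kind != SURVIVAL:
        raise CurveError(f"expected a survival curve, got {curve.kind!r}")
    s = np.asarray(curve.values)
    prev = s[:-1]
    if np.any((prev == 0) & (s[1:] > 0)):
        raise CurveError("survival reaches 0 and then becomes positive")
    with np.errstate(invalid="ignore"):
        p = np.where(prev > 0, 1.0 - s[1:] / np.where(prev > 0, prev, 1.0), 0.0)
    return p


def cumulative_from_annual(p, kind: str) -> CumulativeCurve:
    """Exact inverse of the derivations: build the cumulative curve implied
    by annual probabilities ``p`` (survival ``S[t] = prod(1-p[i])``,
    incidence ``C[t] = 1 - prod(1-p[i])``)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise CurveError("annual probabilities must lie in [0, 1]")
    surv = np.concatenate([[1.0], np.cumprod(1.0 - p)])
    if kind == SURVIVAL:
        return CumulativeCurve(kind=SURVIVAL, values=tuple(surv))
    if kind == INCIDENCE:
        return CumulativeCurve(kind=INCIDENCE, values=tuple(1.0 - surv))
    raise CurveError(f"kind must be '{INCIDENCE}' or '{SURVIVAL}', got {kind!r}")


def write_curve_csv(curve: CumulativeCurve, path) -> None:
    pd.DataFrame(
        {"year": np.arange(curve.horizon + 1), "value": curve.values}
    ).to_csv(path, index=False)


def read_curve_csv(path, kind: str) -> CumulativeCurve:
    df = pd.read_csv(path).sort_values("year")
    return CumulativeCurve(kind=kind, values=tuple(df["value"].to_numpy()))
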