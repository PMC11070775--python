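"""Strength–duration analysis: rheobase and chronaxie from activation thresholds.

The classical Lapicque hyperbola relates the threshold current to the pulse
duration,

    I(d) = I_rh · (1 + c / d),

where I_rh is the rheobase (asymptotic threshold at long pulses) and c the
chronaxie (duration at which the threshold is twice the rheobase).  The
equivalent Weiss charge form, Q(d) = I·d = I_rh·(d + c), is available as an
alternative and is linear in d, so it has a closed-form fit.

Models follow the Model/Results idiom: build a model from (duration,
threshold) points, ``fit()`` returns a results object carrying estimates,
standard errors, residuals and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "Lapicque",
    "WeissCharge",
    "StrengthDurationResults",
    "fit_lapicque",
    "group_thresholds",
]

_CHRONAXIE_MIN_MS = 1e-9


@dataclass
class StrengthDurationResults:
    """Fitted strength–duration parameters with uncertainties."""

    rheobase_uA: float
    chronaxie_ms: float
    rheobase_se_uA: float
    chronaxie_se_ms: float
    rss: float
    n_points: int
    model: str
    at_bound: bool = False
    duration_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold_uA: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, duration_ms: np.ndarray | float) -> np.ndarray:
        d = np.asarray(duration_ms, dtype=float)
        return self.rheobase_uA * (1.0 + self.chronaxie_ms / d)

    def summary(self) -> str:
        lines = [
            f"Strength-duration fit ({self.model})",
            "-" * 44,
            f"{'rheobase (uA)':<22}{self.rheobase_uA:10.4f}  +/- {self.rheobase_se_uA:.4f}",
            f"{'chronaxie (ms)':<22}{self.chronaxie_ms:10.4f}  +/- {self.chronaxie_se_ms:.4f}",
            f"{'n points':<22}{self.n_points:10d}",
            f"{'residual SS':<22}{self.rss:10.4g}",
        ]
        if self.at_bound:
            lines.append("warning: chronaxie at its lower bound (flat curve)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curve on log-duration axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = np.geomspace(self.duration_ms.min(), self.duration_ms.max(), 200)
        ax.plot(self.duration_ms, self.threshold_uA, "o", label="thresholds")
        ax.plot(d, self.predict(d), "-", label=f"{self.model} fit")
        ax.set_xscale("log")
        ax.set_xlabel("pulse duration (ms)")
        ax.set_ylabel("threshold current (uA)")
        ax.legend()
        return ax


class _SDBase:
    name = "base"

    def __init__(self, duration_ms: Sequence[float], threshold_uA: Sequence[float]):
        d = np.asarray(duration_ms, dtype=float)
        i = np.asarray(threshold_uA, dtype=float)
        if d.shape != i.shape or d.ndim != 1:
            raise ValueError("duration and threshold arrays must be 1D and equal length")
        if np.any(d <= 0) or np.any(i <= 0):
            raise ValueError("durations and thresholds must be > 0")
        if np.unique(d).size < 2:
            raise ValueError("underdetermined: need >= 2 distinct pulse durations")
        self.duration_ms = d
        self.threshold_uA = i

    @classmethod
    def from_points(cls, points: Sequence[tuple[float, float]]):
        pts = list(points)
        return cls([p[0] for p in pts], [p[1] for p in pts])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str = "duration_ms",
                       threshold_col: str = "threshold_uA"):
        return cls(df[duration_col].to_numpy(), df[threshold_col].to_numpy())


class Lapicque(_SDBase):
    """Hyperbolic strength–duration model ``I(d) = I_rh (1 + c/d)``.

    Fitted by unweighted nonlinear least squares in current space with a
    deterministic start (rheobase at the minimum threshold, chronaxie at the
    median duration) and positivity bounds; a flat curve drives the chronaxie
    to its lower bound and is flagged.
    """

    name = "lapicque"

    @staticmethod
    def curve(d, irh, c):
        return irh * (1.0 + c / d)

    def fit(self) -> StrengthDurationResults:
        d, i = self.duration_ms, self.threshold_uA
        p0 = [float(i.min()), float(np.median(d))]
        lb = [1e-12, _CHRONAXIE_MIN_MS]
        ub = [np.inf, np.inf]
        with warnings.catch_warnings():
            # exactly determined two-point fits have no covariance estimate
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(self.curve, d, i, p0=p0, bounds=(lb, ub),
                                   maxfev=20000)
        resid = i - self.curve(d, *popt)
        se = np.sqrt(np.diag(pcov))
        return StrengthDurationResults(
            rheobase_uA=float(popt[0]), chronaxie_ms=float(popt[1]),
            rheobase_se_uA=float(se[0]), chronaxie_se_ms=float(se[1]),
            rss=float(resid @ resid), n_points=int(d.size), model=self.name,
            # flat-curve limit: chronaxie negligible on the tested duration scale
            at_bound=bool(popt[1] <= max(10 * _CHRONAXIE_MIN_MS, 1e-4 * d.min())),
            duration_ms=d, threshold_uA=i,
        )


class WeissCharge(_SDBase):
    """Weiss charge form ``Q(d) = I·d = I_rh (d + c)``: linear in duration.

    Closed-form ordinary least squares on charge; slope is the rheobase and
    intercept/slope the chronaxie.
    """

    name = "weiss"

    def fit(self) -> StrengthDurationResults:
        d, i = self.duration_ms, self.threshold_uA
        q = i * d
        A = np.column_stack([d, np.ones_like(d)])
        coef, rss_arr, *_ = np.linalg.lstsq(A, q, rcond=None)
        slope, intercept = coef
        resid = q - A @ coef
        rss = float(resid @ resid)
        n = d.size
        if n > 2:
            s2 = rss / (n - 2)
            cov = s2 * np.linalg.inv(A.T @ A)
            se_slope, se_int = np.sqrt(np.diag(cov))
        else:
            se_slope = se_int = np.nan
        irh = float(slope)
        c = float(intercept / slope) if slope > 0 else np.nan
        at_bound = not (irh > 0 and c > 0)
        if at_bound:
            c = max(c if np.isfinite(c) else _CHRONAXIE_MIN_MS, _CHRONAXIE_MIN_MS)
        # delta-method SE for the chronaxie ratio
        se_c = (
            abs(c) * np.sqrt((se_int / intercept) ** 2 + (se_slope / slope) ** 2)
            if n > 2 and intercept != 0 and slope != 0
            else np.nan
        )
        return StrengthDurationResults(
            rheobase_uA=irh, chronaxie_ms=c,
            rheobase_se_uA=float(se_slope), chronaxie_se_ms=float(se_c),
            rss=rss, n_points=int(n), model=self.name, at_bound=at_bound,
            duration_ms=d, threshold_uA=i,
        )


def fit_lapicque(
    points: Sequence[tuple[float, float]],
    model: str = "lapicque",
) -> StrengthDurationResults:
    """Fit a strength–duration model to (duration_ms, threshold_uA) points."""
    cls = {"lapicque": Lapicque, "weiss": WeissCharge}.get(model)
    if cls is None:
        raise ValueError(f"unknown strength-duration model {model!r}")
    return cls.from_points(points).fit()


def group_thresholds(
    estimates: Sequence,
    groups: Sequence[str],
) -> pd.DataFrame:
    """Per-(group, duration) summary of activation thresholds across cells.

    ``estimates`` are :class:`~retistim.caimg.ThresholdEstimate` objects (or
    anything with ``threshold_uA``, ``duration_us``, ``reached``), paired
    with group labels.  Cells whose threshold was not reached are excluded
    from mean/SD and counted separately.  Sample SD (n−1); SD is reported
    as 0 for n=1 (flagged by the n column).
    """
    if len(estimates) != len(groups):
        raise ValueError("need one group label per threshold estimate")
    rows: dict[tuple[str, float], dict] = {}
    for est, grp in zip(estimates, groups):
        key = (str(grp), float(est.duration_us))
        rec = rows.setdefault(key, {"values": [], "n_not_reached": 0})
        if est.reached and est.threshold_uA is not None:
            rec["values"].append(float(est.threshold_uA))
        else:
            rec["n_not_reached"] += 1
    out = []
    for (grp, dur), rec in sorted(rows.items()):
        vals = np.asarray(rec["values"])
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(dict(
            group=grp, duration_us=dur, threshold_uA_mean=float(vals.mean()),
            threshold_uA_sd=sd, n=int(vals.size),
            n_not_reached=int(rec["n_not_reached"]),
        ))
    return pd.DataFrame(out, columns=["group", "duration_us", "threshold_uA_mean",
                                      "threshold_uA_sd", "n", "n_not_reached"])
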