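"""pYAP-ratio observables, steady-state summaries and curve fits.

The headline observable is the pYAP ratio: the count of phosphorylated YAP
divided by the (constant) total YAP count.  The inside/outside variants count
only pYAP bound within adhesions / free in the cytosol, both still divided by
the total YAP count, so inside + outside = total at every sample.

Two empirical fits are provided: a Hill-type saturation of the steady-state
ratio versus the binding rate, ratio = k1·Rb/(k2+Rb), and an ordinary
least-squares quadratic of the ratio versus the average pairwise distance
between binding sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class TrajectorySeries:
    """Recorded pYAP counts along one run."""

    steps: np.ndarray          # event index at each sample
    times: np.ndarray          # s
    n_pyap_total: np.ndarray
    n_pyap_inside: np.ndarray  # bound within adhesions
    n_pyap_outside: np.ndarray
    n_yap: int                 # constant total molecule count

    def __post_init__(self) -> None:
        for name in ("steps", "times", "n_pyap_total", "n_pyap_inside",
                     "n_pyap_outside"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not np.array_equal(self.n_pyap_inside + self.n_pyap_outside,
                              self.n_pyap_total):
            raise ValueError("inside + outside counts must equal the total")
        if self.n_pyap_total.min(initial=0) < 0 or \
                self.n_pyap_total.max(initial=0) > self.n_yap:
            raise ValueError("pYAP counts must lie in [0, n_yap]")

    @property
    def ratio_total(self) -> np.ndarray:
        return self.n_pyap_total / self.n_yap

    @property
    def ratio_inside(self) -> np.ndarray:
        return self.n_pyap_inside / self.n_yap

    @property
    def ratio_outside(self) -> np.ndarray:
        return self.n_pyap_outside / self.n_yap

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "step": self.steps,
            "time_s": self.times,
            "n_pYAP_total": self.n_pyap_total,
            "n_pYAP_inside": self.n_pyap_inside,
            "n_pYAP_outside": self.n_pyap_outside,
        })


def pyap_ratio(n_pyap: int, n_total: int) -> float:
    """Fraction of YAP molecules that are phosphorylated."""
    if n_total < 1:
        raise ValueError("total YAP count must be >= 1")
    if not 0 <= n_pyap <= n_total:
        raise ValueError(f"pYAP count {n_pyap} outside [0, {n_total}]")
    return n_pyap / n_total


def steady_state_mean(
    values: Sequence[float], burn_in_fraction: float = 0.5
) -> Tuple[float, float]:
    """Mean of the post-burn-in samples plus their SD as a fluctuation scale.

    The first ``burn_in_fraction`` of the samples is discarded as transient;
    the remainder must hold at least 10 samples.
    """
    values = np.asarray(values, dtype=float)
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    start = int(np.floor(len(values) * burn_in_fraction))
    tail = values[start:]
    if len(tail) < 10:
        raise ValueError(
            f"only {len(tail)} post-burn-in samples; need at least 10")
    return float(tail.mean()), float(tail.std(ddof=1))


def aggregate_replicates(means: Sequence[float]) -> Tuple[float, float]:
    """Replicate mean and sample SD (ddof=1); SD is 0 with a warning for n=1."""
    means = np.asarray(means, dtype=float)
    if len(means) == 0:
        raise ValueError("need at least one replicate")
    if len(means) == 1:
        warnings.warn("single replicate: standard deviation reported as 0",
                      stacklevel=2)
        return float(means[0]), 0.0
    return float(means.mean()), float(means.std(ddof=1))


def hill(rb: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Hill-type saturation: ratio = k1·Rb / (k2 + Rb)."""
    return k1 * rb / (k2 + rb)


@dataclass
class HillFit:
    k1: float                  # asymptotic ratio, dimensionless, in [0, 1]
    k2: float                  # half-saturation binding rate, s⁻¹
    residual_ss: float
    n_points: int
    covariance: np.ndarray = field(repr=False, default=None)

    def predict(self, rb) -> np.ndarray:
        return hill(np.asarray(rb, dtype=float), self.k1, self.k2)


@dataclass
class QuadraticFit:
    coefficients: Tuple[float, float, float]  # (c0, c1, c2)
    residual_ss: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        x = np.asarray(x, dtype=float)
        return c0 + c1 * x + c2 * x ** 2


def fit_hill(rb_values: Sequence[float], ratios: Sequence[float]) -> HillFit:
    """Bounded least-squares fit of ratio = k1·Rb/(k2+Rb).

    Multi-start: k1 from the largest observed ratio, k2 from the median Rb
    plus a coarse spread of alternatives; the best-SSE solution wins.
    """
    rb = np.asarray(rb_values, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if len(np.unique(rb)) < 3:
        raise ValueError("need at least 3 distinct binding-rate values")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    k1_0 = min(max(float(y.max()), 1e-6), 1.0)
    k2_med = float(np.median(rb))
    starts = [(k1_0, k2_med)]
    starts += [(k1_0, k2_med * s) for s in (0.1, 10.0)]
    starts += [(min(1.0, 2 * k1_0), k2_med)]
    best = None
    errors = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                hill, rb, y, p0=p0, bounds=([0.0, 0.0], [1.0, np.inf]),
                maxfev=20_000)
        except RuntimeError as exc:  # pragma: no cover - rare
            errors.append(str(exc))
            continue
        ss = float(((hill(rb, *popt) - y) ** 2).sum())
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        raise RuntimeError(
            "Hill fit did not converge from any starting point: "
            + "; ".join(errors))
    ss, popt, pcov = best
    return HillFit(k1=float(popt[0]), k2=float(popt[1]), residual_ss=ss,
                   n_points=len(rb), covariance=pcov)


def fit_quadratic(
    distances: Sequence[float], ratios: Sequence[float]
) -> QuadraticFit:
    """OLS degree-2 polynomial of ratio versus average pairwise distance."""
    x = np.asarray(distances, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct distance values")
    # polynomial.polyfit returns coefficients in increasing degree order
    coeffs, info = np.polynomial.polynomial.polyfit(x, y, 2, full=True)
    resid = info[0]
    ss = float(resid[0]) if len(resid) else 0.0
    return QuadraticFit(coefficients=tuple(float(c) for c in coeffs),
                        residual_ss=ss, n_points=len(x))
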