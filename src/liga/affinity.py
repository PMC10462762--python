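"""Direct ESI-MS affinity measurement: 1:1 protein-ligand Kd from titrations.

In a native-MS titration at fixed protein concentration [P]0, the abundance
ratio R = Ab(PL)/Ab(P) of bound to free protein (charge-state-normalized
peak areas, taken equal to the solution concentration ratio) gives the
fraction of bound protein R/(R+1).  For 1:1 binding the closed form is

    R/(R+1) = ( [P]0 + [L]0 + Kd
                - sqrt( (Kd - [L]0 + [P]0)^2 + 4 Kd [L]0 ) ) / (2 [P]0)

and Kd is obtained by nonlinear least squares of this curve against the
measured fraction bound versus initial ligand concentration [L]0.
Uniform residual weights are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ChargeStateAbundances",
    "TitrationSeries",
    "KdFitResults",
    "KdTitrationModel",
    "abundance_ratio",
    "fraction_bound",
    "fit_kd",
]


@dataclass
class ChargeStateAbundances:
    """Charge-state-normalized peak areas of free (P) and bound (PL) protein."""

    free: dict[int, float]   # charge state -> area of P
    bound: dict[int, float]  # charge state -> area of PL

    def __post_init__(self) -> None:
        for areas in (self.free, self.bound):
            if any(a < 0 for a in areas.values()):
                raise ValueError("peak areas must be non-negative")
        if sum(self.free.values()) <= 0:
            raise ValueError("total free-protein abundance is zero")


def abundance_ratio(ab: ChargeStateAbundances) -> float:
    """R = sum Ab(PL) / sum Ab(P) across charge states."""
    return sum(ab.bound.values()) / sum(ab.free.values())


@dataclass
class TitrationSeries:
    """Fixed [P]0 (uM) and (L0, R) points; R is the bound/free ratio."""

    p0: float
    l0: np.ndarray
    r: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.l0 = np.asarray(self.l0, float)
        self.r = np.asarray(self.r, float)
        if self.p0 <= 0:
            raise ValueError("P0 must be positive")
        if (self.l0 < 0).any() or (self.r < 0).any():
            raise ValueError("L0 and R must be non-negative")
        if self.l0.shape != self.r.shape:
            raise ValueError("L0 and R must have equal length")

    @property
    def fraction(self) -> np.ndarray:
        """Measured fraction bound, R/(R+1)."""
        return self.r / (self.r + 1.0)

    @classmethod
    def from_csv(cls, path, p0: float, label: str = "") -> "TitrationSeries":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.strip().lower(): c for c in df.columns}
        return cls(p0=p0, l0=df[cols["l0"]].to_numpy(),
                   r=df[cols["r"]].to_numpy(), label=label)


def fraction_bound(p0: float, l0, kd: float):
    """Equilibrium fraction of bound protein for 1:1 binding (closed form).

    Monotone increasing in L0 and decreasing in Kd; always in [0, 1].
    """
    if p0 <= 0:
        raise ValueError("P0 must be positive")
    if kd < 0:
        raise ValueError("Kd must be non-negative")
    l0 = np.asarray(l0, float)
    if (l0 < 0).any():
        raise ValueError("L0 must be non-negative")
    f = (p0 + l0 + kd - np.sqrt((kd - l0 + p0) ** 2 + 4.0 * kd * l0)) / (2.0 * p0)
    return np.clip(f, 0.0, 1.0) if f.ndim else float(np.clip(f, 0.0, 1.0))


@dataclass
class KdFitResults:
    """Fitted dissociation constant with Jacobian-based standard error."""

    kd: float
    kd_se: float
    rss: float
    converged: bool
    n_points: int
    series: TitrationSeries

    def summary(self) -> str:
        lines = [
            "1:1 binding model, direct ESI-MS titration",
            "=" * 44,
            f"Series:     {self.series.label or '(unnamed)'}",
            f"P0:         {self.series.p0:g} uM",
            f"n points:   {self.n_points}",
            f"Kd:         {self.kd:.4g} uM",
            f"SE(Kd):     {self.kd_se:.3g} uM",
            f"RSS:        {self.rss:.3g}",
            f"Converged:  {self.converged}",
        ]
        return "\n".join(lines)

    def predict(self, l0) -> np.ndarray:
        return fraction_bound(self.series.p0, l0, self.kd)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.series
        ax.plot(s.l0, s.fraction, "o", label="measured R/(R+1)")
        grid = np.geomspace(max(s.l0.min(), 1e-3), s.l0.max(), 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"fit, Kd = {self.kd:.3g} uM")
        ax.set_xscale("log")
        ax.set_xlabel("[L]0 (uM)")
        ax.set_ylabel("fraction bound")
        ax.legend()
        return ax


class KdTitrationModel:
    """Nonlinear least-squares model of a fraction-bound titration curve.

    Fits in fraction-bound space with uniform weights; Kd is kept positive
    by optimising log10(Kd), initialised from a log-grid search over
    [1e-3, 1e4] uM.
    """

    GRID = np.geomspace(1e-3, 1e4, 57)

    def __init__(self, series: TitrationSeries) -> None:
        if series.l0.size < 3:
            raise ValueError("need at least 3 titration points")
        span = series.l0[series.l0 > 0]
        if span.size == 0 or span.max() / span.min() < 4.0:
            raise ValueError("L0 must span at least a 4-fold range")
        self.series = series

    def _residuals(self, log10_kd: np.ndarray) -> np.ndarray:
        f = fraction_bound(self.series.p0, self.series.l0, 10.0 ** log10_kd[0])
        return f - self.series.fraction

    def fit(self) -> KdFitResults:
        rss_grid = [
            float(np.sum(self._residuals(np.array([np.log10(k)])) ** 2))
            for k in self.GRID
        ]
        k0 = self.GRID[int(np.argmin(rss_grid))]
        sol = least_squares(
            self._residuals,
            x0=[np.log10(k0)],
            bounds=([-6.0], [6.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        converged = bool(sol.success)
        kd = float(10.0 ** sol.x[0]) if converged else float(k0)
        resid = self._residuals(np.array([np.log10(kd)]))
        rss = float(np.sum(resid**2))
        n = resid.size
        kd_se = float("nan")
        if converged and n > 1:
            j = sol.jac.ravel()
            jtj = float(j @ j)
            if jtj > 0:
                # heteroscedasticity-robust (sandwich) variance with a
                # small-sample correction; residual variance is not constant
                # across the titration when noise acts on R
                meat = float(np.sum(j**2 * resid**2)) * n / (n - 1)
                se_log10 = np.sqrt(meat) / jtj
                kd_se = kd * np.log(10.0) * se_log10
        return KdFitResults(
            kd=kd, kd_se=kd_se, rss=rss, converged=converged,
            n_points=n, series=self.series,
        )


def fit_kd(series: TitrationSeries) -> KdFitResults:
    """Functional wrapper: fit Kd from a titration series (see model class)."""
    return KdTitrationModel(series).fit()
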