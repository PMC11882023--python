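"""Incidence-based species richness: Chao2 and rarefaction/extrapolation.

Works on presence/absence of species across T replicated sampling units
(localities within a territory, or territories within the global data set).
The estimand is species richness, the Hill number of order 0.  The Chao2
estimator is a nonparametric lower bound driven by the number of species
seen in exactly one unit (uniques, Q1) and exactly two units (duplicates,
Q2); rarefaction gives the exact combinatorial expectation of richness in a
random subset of t ≤ T units, and extrapolation extends the curve beyond T
towards the Chao2 asymptote.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import derive_rng

__all__ = [
    "IncidenceMatrix",
    "IncidenceFrequencies",
    "RichnessEstimate",
    "RarefactionCurve",
    "tabulate",
    "chao2",
    "rarefy",
    "extrapolate",
    "richness_at",
    "curve_with_ci",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class IncidenceMatrix:
    """Species × sampling-unit 0/1 matrix.

    Species with no incidences are dropped with a warning at construction:
    curated tables sometimes list taxa never found in the surveyed units.
    """

    species: tuple[str, ...]
    units: tuple[str, ...]
    cells: np.ndarray  # shape (S, T), dtype int, values in {0, 1}

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.shape != (len(self.species), len(self.units)):
            raise ValueError("cells shape does not match species/units labels")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("incidence cells must be 0/1")
        empty = arr.sum(axis=1) == 0
        if empty.any():
            dropped = [s for s, e in zip(self.species, empty) if e]
            warnings.warn(
                f"dropping {len(dropped)} species with zero incidences: "
                f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
            object.__setattr__(
                self, "species", tuple(s for s, e in zip(self.species, empty) if not e)
            )
            arr = arr[~empty]
        object.__setattr__(self, "cells", arr.astype(int))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        """Wide 0/1 table: index = species labels, columns = units."""
        return cls(
            species=tuple(map(str, df.index)),
            units=tuple(map(str, df.columns)),
            cells=df.to_numpy(),
        )

    @classmethod
    def from_long(cls, records: Sequence[tuple[str, str]]) -> "IncidenceMatrix":
        """Long (species, unit) occurrence pairs -> wide 0/1 matrix."""
        if not records:
            raise ValueError("no occurrence records")
        df = pd.DataFrame(records, columns=["species", "unit"])
        wide = pd.crosstab(df["species"], df["unit"]).clip(upper=1)
        return cls.from_dataframe(wide.sort_index(axis=0).sort_index(axis=1))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.species), columns=list(self.units))


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Sufficient statistics for incidence-based richness estimation."""

    T: int
    Y: tuple[int, ...]  # per-species incidence counts, each in 1..T
    Q: dict[int, int]  # k -> number of species with incidence count k
    S_obs: int

    def __post_init__(self) -> None:
        if sum(self.Q.values()) != self.S_obs:
            raise ValueError("sum of Q_k must equal S_obs")
        if sum(k * q for k, q in self.Q.items()) != sum(self.Y):
            raise ValueError("sum of k*Q_k must equal total incidences")


@dataclass(frozen=True)
class RichnessEstimate:
    S_obs: int
    S_chao2: float
    se: float
    ci_lower: float
    ci_upper: float
    variant: Literal["classic", "bias_corrected"]


@dataclass(frozen=True)
class RarefactionCurve:
    # rows: (t, estimate, ci_lower, ci_upper, regime)
    points: tuple[tuple[float, float, float, float, str], ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["t", "richness", "ci_lower", "ci_upper", "regime"]
        )


def tabulate(matrix: IncidenceMatrix) -> IncidenceFrequencies:
    """Row sums Y_i and incidence frequency counts Q_k of a 0/1 matrix."""
    if len(matrix.species) == 0 or len(matrix.units) == 0:
        raise ValueError("empty incidence matrix")
    y = matrix.cells.sum(axis=1)
    q = Counter(int(v) for v in y)
    return IncidenceFrequencies(
        T=len(matrix.units), Y=tuple(int(v) for v in y), Q=dict(q), S_obs=len(matrix.species)
    )


def _chao2_point(freq: IncidenceFrequencies, variant: str) -> tuple[float, str]:
    t, q1, q2 = freq.T, freq.Q.get(1, 0), freq.Q.get(2, 0)
    a = (t - 1) / t
    if variant == "auto" or (variant == "classic" and q2 == 0):
        variant = "classic" if q2 > 0 else "bias_corrected"
    if variant == "classic":
        extra = a * q1 * q1 / (2.0 * q2)
    else:
        extra = a * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    return freq.S_obs + extra, variant


def chao2(
    freq: IncidenceFrequencies,
    variant: Literal["auto", "classic", "bias_corrected"] = "auto",
) -> RichnessEstimate:
    """Chao2 richness estimate with analytic variance and log-normal 95% CI.

    Classic form (Q2 > 0): S_obs + ((T−1)/T)·Q1²/(2·Q2); bias-corrected
    form (used when Q2 = 0 or on request):
    S_obs + ((T−1)/T)·Q1·(Q1−1)/(2·(Q2+1)).  The confidence interval is
    placed on D̂ = Ŝ − S_obs on a log scale so its lower bound can never
    fall below the observed richness.
    """
    if freq.T < 2:
        raise ValueError("Chao2 needs at least two sampling units")
    t, q1, q2 = freq.T, freq.Q.get(1, 0), freq.Q.get(2, 0)
    a = (t - 1) / t
    s_hat, used = _chao2_point(freq, variant)
    if q1 == 0:
        return RichnessEstimate(freq.S_obs, float(freq.S_obs), 0.0, float(freq.S_obs), float(freq.S_obs), used)
    if used == "classic":
        r = q1 / q2
        var = q2 * (0.5 * a * r**2 + a**2 * r**3 + 0.25 * a**2 * r**4)
    else:
        var = (
            0.5 * a * q1 * (q1 - 1)
            + 0.25 * a**2 * q1 * (2 * q1 - 1) ** 2
            - 0.25 * a**2 * q1**4 / s_hat
        )
    var = max(var, 0.0)
    se = float(np.sqrt(var))
    d_hat = s_hat - freq.S_obs
    if d_hat > 0 and se > 0:
        k = np.exp(Z95 * np.sqrt(np.log1p(var / d_hat**2)))
        lo, hi = freq.S_obs + d_hat / k, freq.S_obs + d_hat * k
    else:
        lo = hi = s_hat
    return RichnessEstimate(freq.S_obs, float(s_hat), se, float(lo), float(hi), used)


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(freq: IncidenceFrequencies, t: int) -> float:
    """Expected richness in a random subset of t of the T sampling units.

    Exact combinatorial expectation
    S(t) = S_obs − Σ_i C(T−Y_i, t) / C(T, t), the sum running over species
    that can be absent from all t chosen units.  Binomials are evaluated in
    log space so large T is safe.
    """
    if not 1 <= t <= freq.T:
        raise ValueError(f"t={t} outside 1..{freq.T}")
    y = np.asarray(freq.Y, dtype=float)
    can_miss = (freq.T - y) >= t
    if not can_miss.any():
        return float(freq.S_obs)
    miss = np.exp(_log_choose(freq.T - y[can_miss], t) - _log_choose(float(freq.T), t))
    return float(freq.S_obs - miss.sum())


def extrapolate(
    freq: IncidenceFrequencies,
    t_extra: int,
    variant: Literal["auto", "classic", "bias_corrected"] = "auto",
) -> float:
    """Expected richness after t_extra additional units beyond the observed T.

    S(T + t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^t*] with
    Q̂0 = Ŝ_chao2 − S_obs; flat at S_obs when there are no uniques, and
    converging to the Chao2 asymptote as t* → ∞.
    """
    if t_extra < 0:
        raise ValueError("t_extra must be ≥ 0")
    if t_extra == 0:
        return float(freq.S_obs)
    q1 = freq.Q.get(1, 0)
    q0_hat, _ = _chao2_point(freq, variant)
    q0_hat -= freq.S_obs
    if q0_hat <= 0 or q1 == 0:
        return float(freq.S_obs)
    rate = q1 / (q1 + freq.T * q0_hat)
    return float(freq.S_obs + q0_hat * (1.0 - (1.0 - rate) ** t_extra))


def richness_at(freq: IncidenceFrequencies, t: int) -> float:
    """Rarefied (t ≤ T) or extrapolated (t > T) expected richness."""
    return rarefy(freq, t) if t <= freq.T else extrapolate(freq, t - freq.T)


def curve_with_ci(
    matrix: IncidenceMatrix,
    t_grid: Sequence[int],
    n_bootstrap: int = 200,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve with a bootstrap percentile band.

    Point estimates come from the closed forms on the observed matrix and
    do not depend on the seed; the band resamples sampling units with
    replacement and takes the 2.5/97.5 percentiles of the resampled curves.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be ≥ 1")
    freq = tabulate(matrix)
    t_grid = sorted(set(int(t) for t in t_grid))
    if any(t < 1 for t in t_grid):
        raise ValueError("grid values must be ≥ 1")
    points = np.array([richness_at(freq, t) for t in t_grid])

    rng = derive_rng(seed, "curve_bootstrap")
    boot = np.empty((n_bootstrap, len(t_grid)))
    t_units = len(matrix.units)
    for b in range(n_bootstrap):
        cols = rng.integers(0, t_units, size=t_units)
        sub = matrix.cells[:, cols]
        keep = sub.sum(axis=1) > 0
        y = sub[keep].sum(axis=1)
        q = Counter(int(v) for v in y)
        bfreq = IncidenceFrequencies(
            T=t_units, Y=tuple(int(v) for v in y), Q=dict(q), S_obs=int(keep.sum())
        )
        boot[b] = [richness_at(bfreq, t) for t in t_grid]
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)

    rows = []
    for i, t in enumerate(t_grid):
        regime = "observed" if t == freq.T else ("interpolated" if t < freq.T else "extrapolated")
        rows.append((float(t), float(points[i]), float(lo[i]), float(hi[i]), regime))
    return RarefactionCurve(points=tuple(rows))
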