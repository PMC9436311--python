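"""Clone-size distributions, neutral-drift theory and KS comparisons.

A surviving mutation's physical footprint in a biopsy of area B mm^2 is

    clone area = 2 * VAF * B      (clamped at B),

so the filtered variant calls of a biopsy give a sample of clone areas.
Neutral drift of basal progenitors with loss/replacement rate r_lambda per
week predicts, at tissue age t, the clone-size distribution

    P_n(t) = (1 / ln(r_lambda t)) * exp(-n / (r_lambda t)) / n,   n >= 1,

whose heavy-but-exponential tail is conventionally summarized by the first
incomplete moment

    mu_1(n) = (1 / <n>) * sum_{m >= n} m * P(m),

which equals 1 at the smallest size, is nonincreasing, and is log-linear
in n when clone sizes are exponentially distributed.  Two biopsies (or a
biopsy and a simulation) are compared by a two-sample Kolmogorov-Smirnov
test on the clone-size samples, with the classical critical value
D_alpha = c(alpha) * sqrt((m + n) / (m n)).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneSizeDistribution",
    "NeutralTheory",
    "clone_area",
    "neutral_clone_pmf",
    "first_incomplete_moment",
    "ks_compare",
    "KSResult",
    "age_size_summary",
]

#: one cell footprint in mm^2 at the default 15 um cell size; the unit used
#: to discretize clone areas into cell counts.
CELL_FOOTPRINT_MM2 = (15e-3) ** 2


def clone_area(vaf, biopsy_area_mm2: float):
    """Physical clone area 2 * VAF * B in mm^2, clamped at the biopsy area
    (sequencing noise can push VAF past 0.5)."""
    if biopsy_area_mm2 <= 0:
        raise ValueError("biopsy area must be positive")
    v = np.asarray(vaf, dtype=float)
    if np.any(v < 0):
        raise ValueError("VAF must be nonnegative")
    out = np.minimum(2.0 * v * biopsy_area_mm2, biopsy_area_mm2)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class CloneSizeDistribution:
    """Clone areas (mm^2) from one biopsy, with optional mutation ages."""

    areas_mm2: np.ndarray
    biopsy_area_mm2: float
    ages_years: np.ndarray | None = None
    cell_footprint_mm2: float = CELL_FOOTPRINT_MM2

    def __post_init__(self) -> None:
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.areas_mm2.size and (np.any(self.areas_mm2 <= 0)
                                    or np.any(self.areas_mm2 > self.biopsy_area_mm2 + 1e-12)):
            raise ValueError("clone areas must lie in (0, biopsy area]")
        if self.ages_years is not None:
            self.ages_years = np.asarray(self.ages_years, dtype=float)

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, biopsy_area_mm2: float,
                   ages_years=None) -> "CloneSizeDistribution":
        areas = clone_area(calls["vaf_sim"].to_numpy(), biopsy_area_mm2)
        return cls(np.asarray(areas)[np.asarray(areas) > 0], biopsy_area_mm2,
                   ages_years=ages_years)

    @property
    def sizes_cells(self) -> np.ndarray:
        """Clone sizes in discrete cell units (areas binned by one cell
        footprint, minimum 1)."""
        return np.maximum(1, np.rint(self.areas_mm2 / self.cell_footprint_mm2)).astype(np.int64)

    @property
    def mean_size(self) -> float:
        return float(self.sizes_cells.mean())

    @property
    def largest(self) -> int:
        return int(self.sizes_cells.max())

    def __len__(self) -> int:
        return int(self.areas_mm2.size)


@dataclasses.dataclass(frozen=True)
class NeutralTheory:
    """Neutral-drift clone-size theory: basal loss/replacement rate r_lambda
    (per week) at tissue age t (weeks); requires r_lambda * t > 1."""

    r_lambda: float = 0.51
    t_weeks: float = 52.0

    def __post_init__(self) -> None:
        if self.r_lambda * self.t_weeks <= 1.0:
            raise ValueError("r_lambda * t must exceed 1")


def neutral_clone_pmf(n, theory: NeutralTheory):
    """P_n(t) = exp(-n / (r t)) / (n ln(r t)) for integer clone sizes n >= 1."""
    rt = theory.r_lambda * theory.t_weeks
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("clone sizes n must be >= 1")
    out = np.exp(-n_arr / rt) / (n_arr * math.log(rt))
    return float(out) if out.ndim == 0 else out


def first_incomplete_moment(dist: CloneSizeDistribution,
                            n_grid=None) -> pd.DataFrame:
    """Empirical first incomplete moment of a clone-size sample.

    mu_1(n) = (1/<n>) * sum_{m >= n} m * P_hat(m) with P_hat the empirical
    distribution of discretized clone sizes; mu_1 at the smallest size is
    exactly 1 and the curve is nonincreasing.  Returns columns n, mu1.
    """
    if len(dist) < 2:
        raise ValueError("need at least 2 clones")
    sizes = dist.sizes_cells
    if n_grid is None:
        n_grid = np.unique(sizes)
    n_grid = np.asarray(n_grid)
    order = np.sort(sizes)
    # tail sums of m * P(m): cumulative from the top, normalized by <n>
    total = order.sum()
    tail = total - np.concatenate([[0], np.cumsum(order)])[:-1]  # sum of order[i:]
    idx = np.searchsorted(order, n_grid, side="left")
    mu1 = np.where(idx < order.size, tail[np.minimum(idx, order.size - 1)], 0.0) / total
    mu1 = np.where(idx >= order.size, 0.0, mu1)
    return pd.DataFrame({"n": n_grid, "mu1": mu1})


@dataclasses.dataclass(frozen=True)
class KSResult:
    statistic: float       # D_mn
    critical_value: float  # D_alpha
    margin: float          # D_mn - D_alpha (reject if positive)
    reject: bool
    alpha: float


def ks_critical_coefficient(alpha: float) -> float:
    """c(alpha) = sqrt(-ln(alpha/2) / 2); c(0.05) ~= 1.358."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return math.sqrt(-0.5 * math.log(alpha / 2.0))


def ks_compare(dist_a, dist_b, alpha: float = 0.05,
               on: str = "sizes") -> KSResult:
    """Two-sample KS comparison of clone-size samples.

    ``dist_a``/``dist_b`` are :class:`CloneSizeDistribution` or raw sample
    arrays.  ``on='sizes'`` (default) compares the clone-size samples that
    underlie the mu_1 curves; ``on='mu1'`` compares the incomplete-moment
    transformed values instead.  Rejects when D_mn exceeds the critical
    value D_alpha = c(alpha) * sqrt((m + n)/(m n)).
    """
    def extract(d):
        if isinstance(d, CloneSizeDistribution):
            if on == "mu1":
                return first_incomplete_moment(d).mu1.to_numpy()
            return d.sizes_cells.astype(float)
        return np.asarray(d, dtype=float)

    a, b = extract(dist_a), extract(dist_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    d_mn = float(stats.ks_2samp(a, b, method="asymp").statistic)
    m, n = a.size, b.size
    d_alpha = ks_critical_coefficient(alpha) * math.sqrt((m + n) / (m * n))
    return KSResult(statistic=d_mn, critical_value=d_alpha,
                    margin=d_mn - d_alpha, reject=d_mn > d_alpha, alpha=alpha)


def age_size_summary(mutations: pd.DataFrame, age_bins) -> pd.DataFrame:
    """Per-age-bin, per-driver-class clone-area summaries.

    ``mutations`` needs columns age_years, area_mm2 and driver_class
    (passenger / NOTCH1-like / TP53-like).  Returns count, median and upper
    (90%) quantile area per (age bin, driver class); classes with no
    mutations simply contribute no rows.
    """
    age_bins = np.asarray(age_bins, dtype=float)
    df = mutations.copy()
    df["age_bin"] = pd.cut(df["age_years"], bins=age_bins, include_lowest=True)
    grouped = df.groupby(["age_bin", "driver_class"], observed=True)["area_mm2"]
    out = grouped.agg(count="count", median_area_mm2="median",
                      q90_area_mm2=lambda s: s.quantile(0.9)).reset_index()
    return out[out["count"] > 0].reset_index(drop=True)
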