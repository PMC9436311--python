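"""Virtual deep sequencing of simulated clones.

Bulk sequencing of a biopsy never reports the true variant allele
frequency.  The simulated readout mimics a targeted deep-sequencing
pipeline: for mutation i with true frequency

    VAF_t = n_cells_with_mutation / (2 * N_total)

(diploid heterozygous, copy number not tracked), the per-variant depth is
drawn from a patient-specific gamma distribution, D_i ~ Gamma(k_p,
theta_p), rounded to an integer (floor 1); the variant read count is
f_i ~ Binomial(D_i, VAF_t); and the observed frequency is
VAF_s = f_i / D_i.  The gamma depth model is fitted to observed depth
samples by maximum likelihood.  Calls below a VAF cutoff (default 0.005,
the smallest frequency resolvable in comparable patient data) are
filtered out; the cutoff value itself is kept.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthModel",
    "DEFAULT_VAF_CUTOFF",
    "true_vaf",
    "fit_depth_model",
    "sequence_variants",
    "filter_calls",
    "write_variant_table",
    "read_variant_table",
]

DEFAULT_VAF_CUTOFF = 0.005

_TABLE_COLUMNS = ["id", "gene", "vaf_true", "depth", "alt_reads", "vaf_sim"]


@dataclasses.dataclass(frozen=True)
class DepthModel:
    """Gamma model of per-variant sequencing depth: shape k_p, scale theta_p."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean_depth(self) -> float:
        return self.shape * self.scale

    def draw_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Integer depths: gamma draws rounded to nearest int, floored at 1."""
        d = rng.gamma(self.shape, self.scale, size=n)
        return np.maximum(1, np.rint(d)).astype(np.int64)


def true_vaf(n_cells_with_mut, n_total: int):
    """VAF_t = n / (2 N): cells carrying the mutation over twice the
    population size (diploid heterozygous)."""
    if n_total <= 0:
        raise ValueError("population size must be positive")
    n = np.asarray(n_cells_with_mut, dtype=float)
    if np.any(n < 0) or np.any(n > n_total):
        raise ValueError("cell counts must lie in [0, N]")
    out = n / (2.0 * n_total)
    return float(out) if out.ndim == 0 else out


def fit_depth_model(depth_samples) -> DepthModel:
    """Gamma maximum-likelihood fit (location fixed at zero) to observed
    per-variant depths.

    Requires at least 30 strictly positive samples; constant samples raise
    (the gamma MLE degenerates — fall back to a moment fit by hand if that
    is really what you want).  The optimizer starts from the moment-matched
    parameters, so the optimum's log-likelihood is never below that start.
    """
    d = np.asarray(depth_samples, dtype=float)
    if d.size < 30:
        raise ValueError("need at least 30 depth samples")
    if np.any(d <= 0):
        raise ValueError("depths must be positive")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate (constant) depth samples; use a moment fit instead")
    shape, _, scale = stats.gamma.fit(d, floc=0)
    return DepthModel(shape=float(shape), scale=float(scale))


def sequence_variants(clone_table: pd.DataFrame, depth_model: DepthModel,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the sequencing readout for a clone table.

    ``clone_table`` needs columns ``id`` and ``vaf_true`` (extra columns such
    as ``gene`` pass through).  Depths are drawn independently per variant.
    Returns the variant-call table with columns id, gene, vaf_true, depth,
    alt_reads, vaf_sim.
    """
    n = len(clone_table)
    vaf_t = clone_table["vaf_true"].to_numpy(dtype=float)
    if np.any((vaf_t < 0) | (vaf_t > 1)):
        raise ValueError("vaf_true must lie in [0, 1]")
    depths = depth_model.draw_depths(n, rng)
    alt = rng.binomial(depths, vaf_t)
    out = pd.DataFrame({
        "id": clone_table["id"].to_numpy(),
        "gene": clone_table["gene"].to_numpy() if "gene" in clone_table else ["."] * n,
        "vaf_true": vaf_t,
        "depth": depths,
        "alt_reads": alt,
        "vaf_sim": alt / depths,
    })
    return out


def filter_calls(table: pd.DataFrame, cutoff: float = DEFAULT_VAF_CUTOFF) -> pd.DataFrame:
    """Drop calls with simulated VAF below the cutoff (VAF >= cutoff kept)."""
    return table[table["vaf_sim"] >= cutoff].reset_index(drop=True)


def write_variant_table(table: pd.DataFrame, path) -> None:
    table.loc[:, [c for c in _TABLE_COLUMNS if c in table.columns]].to_csv(
        path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant-call table TSV (same dialect accepted for patient
    VAF tables; only a ``vaf_sim`` or ``vaf`` column is strictly required)."""
    df = pd.read_csv(path, sep="\t")
    if "vaf_sim" not in df.columns:
        if "vaf" in df.columns:
            df = df.rename(columns={"vaf": "vaf_sim"})
        else:
            raise ValueError("variant table needs a vaf_sim (or vaf) column")
    return df
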