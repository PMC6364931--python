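"""Environment-level r-K relationship analyses.

Within one environment the Spearman rank correlation between r and K across
genotypes (rho_rK) measures whether the two traits trade off (negative) or
trade up (positive).  Environment quality Q is the mean r of all genotypes
in the environment; across environments, rho_rK falls as Q rises.  Binning
genotypes by r and locating the bin with the highest mean K gives the
turning-point growth rate r_tp at which raising r stops raising K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputDataError, UndefinedStatisticError

__all__ = [
    "EnvironmentSummary",
    "TurningPoint",
    "spearman",
    "summarize_environment",
    "summaries_frame",
    "cross_environment_trend",
    "bin_by_r",
    "turning_point",
]


@dataclass(frozen=True)
class EnvironmentSummary:
    environment: str
    Q: float  # mean r over all genotypes
    mean_K: float
    rho_rK: float
    p_rho: float
    n_genotypes: int


@dataclass(frozen=True)
class TurningPoint:
    """Mean, across environments, of the mean r of each environment's
    highest-mean-K bin of genotypes."""

    r_tp: float
    per_environment_peaks: tuple[tuple[str, float], ...]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Returns (rho, two-sided p) where p uses the large-sample t
    approximation.  Constant inputs have no defined rank correlation and
    raise :class:`UndefinedStatisticError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputDataError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise InputDataError(f"need at least 3 observations, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputDataError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def summarize_environment(traits: pd.DataFrame) -> EnvironmentSummary:
    """Summarize one environment's slice of the trait table.

    Q and mean_K are unweighted means over genotypes; rho_rK and its p-value
    come from :func:`spearman` over the genotype-level (r, K) pairs.
    """
    envs = traits["environment"].unique()
    if len(envs) != 1:
        raise InputDataError(f"expected one environment, got {list(envs)}")
    if len(traits) < 3:
        raise InputDataError(f"need at least 3 genotypes, got {len(traits)}")
    rho, p = spearman(traits["r"].to_numpy(), traits["K"].to_numpy())
    return EnvironmentSummary(
        environment=str(envs[0]),
        Q=float(traits["r"].mean()),
        mean_K=float(traits["K"].mean()),
        rho_rK=rho,
        p_rho=p,
        n_genotypes=len(traits),
    )


def summaries_frame(summaries: list[EnvironmentSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "environment": [s.environment for s in summaries],
            "n": [s.n_genotypes for s in summaries],
            "Q": [s.Q for s in summaries],
            "mean_K": [s.mean_K for s in summaries],
            "rho_rK": [s.rho_rK for s in summaries],
            "p": [s.p_rho for s in summaries],
        }
    )


def cross_environment_trend(
    summaries: list[EnvironmentSummary],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Across-environment Spearman of (Q, rho_rK) and of (mean_K, rho_rK)."""
    if len(summaries) < 3:
        raise InputDataError(f"need at least 3 environments, got {len(summaries)}")
    q = [s.Q for s in summaries]
    mk = [s.mean_K for s in summaries]
    rr = [s.rho_rK for s in summaries]
    return spearman(q, rr), spearman(mk, rr)


def bin_by_r(traits: pd.DataFrame, bin_size: int = 500) -> pd.DataFrame:
    """Bin one environment's genotypes by ascending r into bins of exactly
    ``bin_size``; a trailing partial bin is discarded.

    Ties in r are broken by genotype label so the binning is reproducible.
    Returns a frame with environment, bin_index, n, mean_r, mean_K.
    """
    envs = traits["environment"].unique()
    if len(envs) != 1:
        raise InputDataError(f"expected one environment, got {list(envs)}")
    if bin_size < 1:
        raise InputDataError(f"bin_size must be >= 1, got {bin_size}")
    n = len(traits)
    if n < bin_size:
        raise InputDataError(f"{n} genotypes is fewer than bin_size={bin_size}")
    s = traits.sort_values(["r", "genotype"], kind="mergesort").reset_index(drop=True)
    n_bins = n // bin_size
    rows = []
    for b in range(n_bins):
        chunk = s.iloc[b * bin_size : (b + 1) * bin_size]
        rows.append(
            {
                "environment": str(envs[0]),
                "bin_index": b,
                "n": bin_size,
                "mean_r": float(chunk["r"].mean()),
                "mean_K": float(chunk["K"].mean()),
            }
        )
    return pd.DataFrame(rows)


def turning_point(bins: pd.DataFrame) -> TurningPoint:
    """Average, over environments, of the mean r of the highest-mean-K bin.

    A tie in mean K is broken toward the lower bin index (the lower-r bin).
    """
    if len(bins) == 0:
        raise InputDataError("turning_point requires at least one bin")
    peaks = []
    for env, grp in bins.groupby("environment", sort=True):
        grp = grp.sort_values("bin_index")
        i = int(np.argmax(grp["mean_K"].to_numpy()))  # argmax takes the first max
        peaks.append((str(env), float(grp["mean_r"].iloc[i])))
    r_tp = float(np.mean([p[1] for p in peaks]))
    return TurningPoint(r_tp=r_tp, per_environment_peaks=tuple(peaks))
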