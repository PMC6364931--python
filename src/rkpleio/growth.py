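"""Logistic growth-curve estimation of r and K with quality control.

Each replicate is a time series of cell counts N(t).  The logistic solution

    N(t) = K / (1 + (K/N0 - 1) e^{-r t})

is fitted by unweighted least squares, estimating all three parameters
(N0, r, K) jointly.  Replicates are filtered per environment by fold-change
windows around the median r (50%-200%) and median K (25%-400%), and the
retained replicates are averaged into genotype-level trait values with
standard errors.

The optimizer is a vectorized Levenberg-Marquardt on (log N0, r, log K):
the log scale keeps N0 and K positive and well conditioned across the five
orders of magnitude a growth curve spans, and batching lets tens of
thousands of replicates (one simulated screen) be fitted in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputDataError

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "logistic",
    "fit_logistic",
    "fit_logistic_batch",
    "fit_many",
    "qc_filter",
    "aggregate_genotypes",
    "STANDARD_TIMES",
]

# 217 time points, 0-72 h at 20-min intervals: the standard scan grid.
STANDARD_TIMES = np.linspace(0.0, 72.0, 217)

R_BOUND = 10.0  # per hour; fits pinned here are flagged unconverged
# K is bounded by 1e4 x the max observed count: wide enough that a curve cut
# off far from saturation (e.g. r=0.02, K=1e7 observed only to ~4e3 cells at
# 72 h) can still be recovered, while runaway fits are flagged unconverged.
K_FOLD_BOUND = 1e4


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's growth time series for one genotype in one environment."""

    environment: str
    genotype: str
    replicate: int
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise InputDataError("times and counts must be 1-D and of equal length")
        if len(t) < 10:
            raise InputDataError(f"at least 10 time points required, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise InputDataError("times must be strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise InputDataError("counts must be finite and non-negative")


@dataclass
class LogisticFit:
    """Fitted logistic parameters for one replicate.

    R_g2 is left unclipped (it can be negative for terrible fits, and NaN
    when the counts are constant so SST = 0); such fits are weeded out by
    the r/K quality windows rather than by clipping.
    """

    environment: str
    genotype: str
    replicate: int
    N0: float
    r: float
    K: float
    R_g2: float
    SST: float
    converged: bool
    retained: bool = False


def logistic(t, N0: float, r: float, K: float):
    """Logistic population size at time t."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-r * t))


def _initial_guesses(t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Data-driven starts: N0 = first count (floored at 1), K = max count,
    r = log-count slope over the first quarter of time points."""
    m, n = Y.shape
    N0g = np.maximum(Y[:, 0], 1.0)
    Kg = np.maximum(Y.max(axis=1), np.maximum(N0g * 1.001, 2.0))
    q = max(n // 4, 2)
    tq = t[:q]
    tc = tq - tq.mean()
    ylog = np.log(np.maximum(Y[:, :q], 1e-9))
    slope = (ylog * tc).sum(axis=1) / (tc * tc).sum()
    rg = np.clip(slope, 1e-3, 5.0)
    return np.column_stack([np.log(N0g), rg, np.log(Kg)])


def _three_point_guesses(t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Closed-form starts from three equally spaced points.

    1/N(t) decays exponentially toward 1/K, so for points at t0, t0+d,
    t0+2d with reciprocals z1, z2, z3:
        1/K = (z2^2 - z1 z3) / (2 z2 - z1 - z3),   e^{-rd} = (z2-z3)/(z1-z2).
    Exact on noise-free data; used as a fallback start when the data-driven
    start stalls (e.g. curves far from saturation where K is weakly
    identified).  Invalid formulas fall back to the data-driven guess.
    """
    m = (Y.shape[1] - 1) // 2
    d = t[m] - t[0]
    with np.errstate(all="ignore"):
        z1 = 1.0 / np.maximum(Y[:, 0], 1e-12)
        z2 = 1.0 / np.maximum(Y[:, m], 1e-12)
        z3 = 1.0 / np.maximum(Y[:, 2 * m], 1e-12)
        invK = (z2 * z2 - z1 * z3) / (2.0 * z2 - z1 - z3)
        ratio = (z2 - z3) / (z1 - z2)
        r = -np.log(ratio) / d
    base = _initial_guesses(t, Y)
    ok = np.isfinite(invK) & (invK > 0) & np.isfinite(r) & (r > 0) & (r < R_BOUND)
    K = np.where(ok, 1.0 / np.where(ok, invK, 1.0), np.exp(base[:, 2]))
    K = np.maximum(K, np.maximum(Y[:, 0], 1.0) * 1.001)
    r = np.where(ok, r, base[:, 1])
    out = base.copy()
    out[:, 1] = r
    out[:, 2] = np.log(K)
    return out


def _residual_and_jacobian(theta: np.ndarray, t: np.ndarray, Y: np.ndarray):
    """Residuals and Jacobian of the logistic model in (log N0, r, log K).

    With B = K/N0 - 1, E = e^{-rt}, D = 1 + B E and N = K/D:
      dN/dlogN0 = K^2 E / (N0 D^2)
      dN/dr     = K B t E / D^2
      dN/dlogK  = (K/D) (1 - K E / (N0 D))
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        N0 = np.exp(theta[:, 0:1])
        r = theta[:, 1:2]
        K = np.exp(theta[:, 2:3])
        E = np.exp(-r * t[None, :])
        B = K / N0 - 1.0
        D = 1.0 + B * E
        N = K / D
        R = N - Y
        dlogN0 = K * K * E / (N0 * D * D)
        dr = K * B * t[None, :] * E / (D * D)
        dlogK = (K / D) * (1.0 - K * E / (N0 * D))
        J = np.stack([dlogN0, dr, dlogK], axis=2)
    return R, J


def _lm_solve(t: np.ndarray, Y: np.ndarray, theta0: np.ndarray, max_iter: int = 200):
    """Batched Levenberg-Marquardt.  Returns (theta, sse, converged)."""
    m = Y.shape[0]
    theta = theta0.copy()
    log_k_hi = np.log(np.maximum(Y.max(axis=1), 2.0) * K_FOLD_BOUND)
    log_n0_hi = np.log(np.maximum(Y.max(axis=1), 2.0))

    def clip(th):
        th[:, 0] = np.minimum(th[:, 0], log_n0_hi[idx] if th.shape[0] != m else log_n0_hi)
        th[:, 1] = np.clip(th[:, 1], 0.0, R_BOUND)
        th[:, 2] = np.minimum(th[:, 2], log_k_hi[idx] if th.shape[0] != m else log_k_hi)
        return th

    idx = np.arange(m)
    theta = clip(theta)
    R, J = _residual_and_jacobian(theta, t, Y)
    sse = np.einsum("ij,ij->i", R, R)
    bad = ~np.isfinite(sse)
    sse[bad] = np.inf
    lam = np.full(m, 1e-3)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    eye = np.eye(3)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        Ja, Ra = J[idx], R[idx]
        good = np.isfinite(Ja).all(axis=(1, 2)) & np.isfinite(Ra).all(axis=1)
        Ja = np.where(good[:, None, None], Ja, 0.0)
        Ra = np.where(good[:, None], Ra, 0.0)
        JT = Ja.transpose(0, 2, 1)
        A = JT @ Ja
        g = (JT @ Ra[:, :, None])[:, :, 0]
        # Marquardt scaling: damp relative to the diagonal magnitude
        diag = np.maximum(A[:, (0, 1, 2), (0, 1, 2)].max(axis=1), 1e-30)
        A = A + (lam[idx] * diag)[:, None, None] * eye[None]
        try:
            step = np.linalg.solve(A, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(A[i], g[i], rcond=None)[0] for i in range(len(idx))]
            )
        th_new = theta[idx] - step
        th_new = clip(th_new)
        R_new, J_new = _residual_and_jacobian(th_new, t, Y[idx])
        sse_new = np.einsum("ij,ij->i", R_new, R_new)
        sse_new[~np.isfinite(sse_new)] = np.inf
        better = sse_new <= sse[idx]
        scale = np.maximum(np.abs(theta[idx]), 1.0)
        small = (np.abs(step) / scale).max(axis=1) < 1e-12
        rel_impr = (sse[idx] - sse_new) <= 1e-14 * np.maximum(sse[idx], 1e-300)
        done = better & (small | rel_impr)

        upd = np.nonzero(better)[0]
        gi = idx[upd]
        theta[gi] = th_new[upd]
        R[gi] = R_new[upd]
        J[gi] = J_new[upd]
        sse[gi] = sse_new[upd]
        lam[gi] = np.maximum(lam[gi] * 0.3, 1e-14)
        wi = idx[~better]
        lam[wi] *= 5.0

        converged[idx[done]] = True
        stalled = lam[idx] > 1e12
        active[idx[done | stalled]] = False

    return theta, sse, converged


def fit_logistic_batch(
    times: np.ndarray, counts: np.ndarray, chunk: int = 20000
) -> pd.DataFrame:
    """Fit many replicates sharing one time grid.

    counts: (n_curves, n_times).  Returns a DataFrame with columns
    N0, r, K, R_g2, SST, converged (row order preserved).
    """
    t = np.asarray(times, dtype=float)
    Y = np.asarray(counts, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if len(t) < 10:
        raise InputDataError(f"at least 10 time points required, got {len(t)}")
    if not np.all(np.diff(t) > 0):
        raise InputDataError("times must be strictly increasing")
    if not np.all(np.isfinite(Y)) or np.any(Y < 0):
        raise InputDataError("counts must be finite and non-negative")

    # zero counts at t=0 are replaced by the smallest positive observed count
    zero0 = Y[:, 0] == 0
    if zero0.any():
        Y = Y.copy()
        for i in np.nonzero(zero0)[0]:
            pos = Y[i][Y[i] > 0]
            Y[i, 0] = pos.min() if len(pos) else 1.0

    out = []
    for lo in range(0, Y.shape[0], chunk):
        Yc = Y[lo : lo + chunk]
        theta0 = _initial_guesses(t, Yc)
        theta, sse, conv = _lm_solve(t, Yc, theta0)
        # second chance from the three-point closed-form start
        retry = np.nonzero(~conv)[0]
        if len(retry):
            theta2, sse2, conv2 = _lm_solve(
                t, Yc[retry], _three_point_guesses(t, Yc[retry])
            )
            take = conv2 | (sse2 < sse[retry])
            theta[retry[take]] = theta2[take]
            sse[retry[take]] = sse2[take]
            conv[retry[take]] = conv2[take]
        N0 = np.exp(theta[:, 0])
        r = theta[:, 1]
        K = np.exp(theta[:, 2])
        # boundary-pinned solutions are not trusted
        kmax = np.maximum(Yc.max(axis=1), 2.0)
        pinned = (r >= R_BOUND - 1e-9) | (K >= kmax * K_FOLD_BOUND * (1 - 1e-9))
        conv = conv & ~pinned & np.isfinite(sse)
        sst = ((Yc - Yc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - sse / sst
        out.append(
            pd.DataFrame(
                {"N0": N0, "r": r, "K": K, "R_g2": r2, "SST": sst, "converged": conv}
            )
        )
    return pd.concat(out, ignore_index=True)


def fit_logistic(curve: GrowthCurve, init: Optional[Sequence[float]] = None) -> LogisticFit:
    """Least-squares logistic fit of one replicate.

    ``init`` optionally overrides the data-driven starting values
    (N0, r, K).  Optimizer failure is reported via ``converged=False``,
    never an exception.
    """
    t = curve.times
    Y = curve.counts[None, :].astype(float)
    if Y[0, 0] == 0:
        pos = Y[0][Y[0] > 0]
        Y = Y.copy()
        Y[0, 0] = pos.min() if len(pos) else 1.0
    if init is not None:
        N0g, rg, Kg = init
        theta0 = np.array([[np.log(max(N0g, 1e-12)), rg, np.log(max(Kg, 1e-12))]])
        theta, sse, conv = _lm_solve(t, Y, theta0)
    else:
        theta, sse, conv = _lm_solve(t, Y, _initial_guesses(t, Y))
        if not conv[0]:
            theta2, sse2, conv2 = _lm_solve(t, Y, _three_point_guesses(t, Y))
            if conv2[0] or sse2[0] < sse[0]:
                theta, sse, conv = theta2, sse2, conv2
    N0, r, K = float(np.exp(theta[0, 0])), float(theta[0, 1]), float(np.exp(theta[0, 2]))
    kmax = max(Y.max(), 2.0)
    pinned = (r >= R_BOUND - 1e-9) or (K >= kmax * K_FOLD_BOUND * (1 - 1e-9))
    converged = bool(conv[0]) and not pinned and np.isfinite(sse[0])
    sst = float(((Y[0] - Y[0].mean()) ** 2).sum())
    r2 = 1.0 - float(sse[0]) / sst if sst > 0 else float("nan")
    return LogisticFit(
        environment=curve.environment,
        genotype=curve.genotype,
        replicate=curve.replicate,
        N0=N0,
        r=r,
        K=K,
        R_g2=r2,
        SST=sst,
        converged=converged,
    )


def fit_many(curves: Iterable[GrowthCurve]) -> list[LogisticFit]:
    """Fit a collection of replicates, batching those that share a time grid."""
    curves = list(curves)
    groups: dict[bytes, list[int]] = {}
    for i, c in enumerate(curves):
        groups.setdefault(c.times.tobytes(), []).append(i)
    fits: list[Optional[LogisticFit]] = [None] * len(curves)
    for key, idxs in groups.items():
        t = curves[idxs[0]].times
        Y = np.stack([curves[i].counts for i in idxs])
        res = fit_logistic_batch(t, Y)
        for row, i in enumerate(idxs):
            c = curves[i]
            fits[i] = LogisticFit(
                environment=c.environment,
                genotype=c.genotype,
                replicate=c.replicate,
                N0=float(res.N0.iloc[row]),
                r=float(res.r.iloc[row]),
                K=float(res.K.iloc[row]),
                R_g2=float(res.R_g2.iloc[row]),
                SST=float(res.SST.iloc[row]),
                converged=bool(res.converged.iloc[row]),
            )
    return fits  # type: ignore[return-value]


def qc_filter(
    fits: Sequence[LogisticFit],
    r_window: tuple[float, float] = (0.5, 2.0),
    K_window: tuple[float, float] = (0.25, 4.0),
) -> list[LogisticFit]:
    """Set retained flags for all fits of one environment.

    Medians of r and K are taken over all converged fits in the environment;
    a replicate is retained iff it converged and its r lies within
    [0.5, 2] x median(r) and its K within [0.25, 4] x median(K).  Unconverged
    fits are never retained.  Idempotent: the medians are always computed
    over converged fits, not over previously retained ones.
    """
    fits = list(fits)
    if not fits:
        raise InputDataError("qc_filter requires at least one fit")
    envs = {f.environment for f in fits}
    if len(envs) > 1:
        raise InputDataError(f"qc_filter expects one environment, got {sorted(envs)}")
    conv = [f for f in fits if f.converged]
    if not conv:
        raise InputDataError("qc_filter requires at least one converged fit")
    med_r = float(np.median([f.r for f in conv]))
    med_K = float(np.median([f.K for f in conv]))
    out = []
    for f in fits:
        ok = (
            f.converged
            and r_window[0] * med_r <= f.r <= r_window[1] * med_r
            and K_window[0] * med_K <= f.K <= K_window[1] * med_K
        )
        out.append(
            LogisticFit(
                environment=f.environment,
                genotype=f.genotype,
                replicate=f.replicate,
                N0=f.N0,
                r=f.r,
                K=f.K,
                R_g2=f.R_g2,
                SST=f.SST,
                converged=f.converged,
                retained=ok,
            )
        )
    return out


def aggregate_genotypes(fits: Sequence[LogisticFit], min_reps: int = 1) -> pd.DataFrame:
    """Average retained replicates into genotype-level trait values.

    Returns the trait table (one row per environment x genotype) with
    columns environment, genotype, r, K, se_r, se_K, n_retained, R_g2.
    Standard errors are sample SD / sqrt(n) and are NaN for n_retained < 2.
    Genotypes with fewer than ``min_reps`` retained replicates are omitted.
    """
    rows = [
        (f.environment, f.genotype, f.r, f.K, f.R_g2)
        for f in fits
        if f.retained
    ]
    if not rows:
        return pd.DataFrame(
            columns=["environment", "genotype", "r", "K", "se_r", "se_K", "n_retained", "R_g2"]
        )
    df = pd.DataFrame(rows, columns=["environment", "genotype", "r", "K", "R_g2"])
    g = df.groupby(["environment", "genotype"], sort=True)
    agg = g.agg(
        r=("r", "mean"),
        K=("K", "mean"),
        se_r=("r", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan),
        se_K=("K", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan),
        n_retained=("r", "size"),
        R_g2=("R_g2", "mean"),
    ).reset_index()
    agg = agg[agg.n_retained >= min_reps].reset_index(drop=True)
    return agg[["environment", "genotype", "r", "K", "se_r", "se_K", "n_retained", "R_g2"]]
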