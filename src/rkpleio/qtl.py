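"""Iterative QTL mapping with permutation FDR and pleiotropy classification.

Genotypes of a biparental diploid cross are coded 0/1/2 (copies of one
parental allele).  Mapping proceeds in rounds: in each round the working
phenotype is the residual of the raw phenotype on all previously accepted
QTLs, each chromosome nominates its most strongly associated SNP (additive
OLS t-test), and nominees are accepted when their permutation-based q-value
is at or below the FDR threshold.  With 16 chromosomes and 6 rounds at most
96 QTLs can be mapped per trait.  Accepted sets are thinned to the top k by
greedy backward elimination on joint variance explained, compared against
random SNP sets of the same size, and classified as concordant or
antagonistic by the signs of their joint-regression effects on r and K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputDataError, UndefinedStatisticError

__all__ = [
    "GenotypeMatrix",
    "QTLRecord",
    "prune_complete_ld",
    "snp_association",
    "map_qtls",
    "variance_explained",
    "prune_to_top_k",
    "random_snp_baseline",
    "qtl_effects",
    "segment_enrichment",
    "representative_snp_effect",
    "records_frame",
]


@dataclass
class GenotypeMatrix:
    """SNP x genotype codes in {0, 1, 2} with a chromosome/position map.

    codes: float array of shape (n_snps, n_genotypes); missing values NaN.
    Positions are 1-based bp and strictly increasing within a chromosome.
    """

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    codes: np.ndarray
    genotype_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.chromosomes = np.asarray(self.chromosomes)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=float)
        self.genotype_ids = np.asarray(self.genotype_ids)
        n_snps = len(self.snp_ids)
        if self.codes.shape != (n_snps, len(self.genotype_ids)):
            raise InputDataError("codes must be (n_snps, n_genotypes)")
        if len(self.chromosomes) != n_snps or len(self.positions) != n_snps:
            raise InputDataError("chromosome/position arrays must match snp_ids")
        vals = self.codes[np.isfinite(self.codes)]
        if not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise InputDataError("codes must be 0, 1, 2 or missing (NaN)")
        for c in np.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == c]
            if not np.all(np.diff(pos) > 0):
                raise InputDataError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def imputed(self) -> np.ndarray:
        """Codes with missing values mean-imputed per SNP."""
        X = self.codes.copy()
        missing = ~np.isfinite(X)
        if missing.any():
            means = np.nanmean(np.where(missing, np.nan, X), axis=1)
            means = np.where(np.isfinite(means), means, 0.0)
            rows, cols = np.nonzero(missing)
            X[rows, cols] = means[rows]
        return X

    def subset(self, snp_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(snp_indices, dtype=int)
        return GenotypeMatrix(
            snp_ids=self.snp_ids[idx],
            chromosomes=self.chromosomes[idx],
            positions=self.positions[idx],
            codes=self.codes[idx],
            genotype_ids=self.genotype_ids,
        )


@dataclass
class QTLRecord:
    snp_id: str
    chromosome: str
    position: int
    trait: str
    environment: str
    round: int
    stat: float
    p: float
    effect_r: float = float("nan")
    effect_K: float = float("nan")
    pleiotropy: str = "null"
    snp_index: int = field(default=-1, repr=False)  # row in the mapping matrix


def records_frame(records: Sequence[QTLRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "environment": [q.environment for q in records],
            "trait": [q.trait for q in records],
            "round": [q.round for q in records],
            "snp_id": [q.snp_id for q in records],
            "chrom": [q.chromosome for q in records],
            "pos": [q.position for q in records],
            "stat": [q.stat for q in records],
            "p": [q.p for q in records],
            "effect_r": [q.effect_r for q in records],
            "effect_K": [q.effect_K for q in records],
            "pleiotropy": [q.pleiotropy for q in records],
        }
    )


def prune_complete_ld(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse runs of consecutive SNPs in complete LD to their middle SNP.

    A run is a maximal block of consecutive SNPs on one chromosome whose
    genotype-code vectors are identical (missing patterns included); the
    middle member is kept, the lower middle for an even run.
    """
    keep = []
    i = 0
    n = gm.n_snps
    while i < n:
        j = i
        while (
            j + 1 < n
            and gm.chromosomes[j + 1] == gm.chromosomes[i]
            and np.array_equal(gm.codes[j + 1], gm.codes[i], equal_nan=True)
        ):
            j += 1
        keep.append(i + (j - i) // 2)
        i = j + 1
    return gm.subset(keep)


def snp_association(phenotype, codes) -> tuple[float, float, float]:
    """Additive OLS association of one SNP: returns (|t|, two-sided p, slope).

    Missing codes are mean-imputed; a monomorphic SNP returns (0, 1, 0).
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(codes, dtype=float)
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    miss = ~np.isfinite(x)
    if miss.any():
        m = x[~miss].mean() if (~miss).any() else 0.0
        x = np.where(miss, m, x)
    n = len(y)
    if n < 10:
        raise InputDataError(f"need >= 10 genotypes with data, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return 0.0, 1.0, 0.0
    yc = y - y.mean()
    slope = float(xc @ yc) / sxx
    sse = float(yc @ yc) - slope * float(xc @ yc)
    dof = n - 2
    s2 = max(sse, 0.0) / dof
    if s2 == 0.0:
        return float("inf"), 0.0, slope
    t = slope / np.sqrt(s2 / sxx)
    p = 2.0 * stats.t.sf(abs(t), dof)
    return abs(float(t)), float(p), slope


def _all_snp_stats(Xc: np.ndarray, sxx: np.ndarray, y: np.ndarray):
    """|t| statistics of every SNP against one phenotype.

    Xc: per-SNP centered, imputed codes (n_snps, n_gen); sxx its row sums of
    squares.  Returns (|t|, slope) arrays; monomorphic SNPs get |t| = 0.
    """
    n = Xc.shape[1]
    yc = y - y.mean()
    sxy = Xc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        sse = float(yc @ yc) - slope * sxy
        s2 = np.maximum(sse, 0.0) / (n - 2)
        denom = np.sqrt(s2 / np.where(sxx > 0, sxx, 1.0))
        t = np.where((sxx > 0) & (denom > 0), np.abs(slope) / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where((sxx > 0) & (denom == 0) & (np.abs(slope) > 0), np.inf, t)
    return t, slope


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, X] via least squares (least-norm if collinear)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ beta


def map_qtls(
    phenotype,
    gm: GenotypeMatrix,
    trait: str = "trait",
    environment: str = "env",
    max_rounds: int = 6,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[QTLRecord]:
    """Iterative per-chromosome QTL mapping with a permutation FDR.

    Per round: the working phenotype is the residual of the raw phenotype on
    all previously accepted QTL codes (round 1 uses the raw phenotype); each
    chromosome's candidate is its largest-|t| SNP not yet accepted (tie
    broken toward the smaller position); the q-value of a candidate with
    statistic s is

        mean over permutations of #(permuted chromosome-best |t| >= s)
        -----------------------------------------------------------------
        #(real candidates this round with |t| >= s)

    where each permutation shuffles the working phenotype across genotypes
    and records every chromosome's best |t|.  Candidates with q <= fdr are
    accepted.  Mapping stops after ``max_rounds`` or on a round that accepts
    nothing.
    """
    if n_perm < 20:
        raise ConfigurationError(f"n_perm must be >= 20, got {n_perm}")
    if max_rounds < 1:
        raise ConfigurationError(f"max_rounds must be >= 1, got {max_rounds}")
    y0 = np.asarray(phenotype, dtype=float)
    if len(y0) != gm.n_genotypes:
        raise InputDataError("phenotype length must equal number of genotypes")
    if not np.all(np.isfinite(y0)):
        raise InputDataError("phenotype must be finite")

    rng = np.random.default_rng(seed)
    X = gm.imputed()
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    chroms = gm.chromosomes
    chrom_labels = list(dict.fromkeys(chroms.tolist()))  # preserve map order
    chrom_idx = {c: np.nonzero(chroms == c)[0] for c in chrom_labels}
    n = gm.n_genotypes

    accepted: list[QTLRecord] = []
    accepted_idx: list[int] = []

    for rnd in range(1, max_rounds + 1):
        if accepted_idx:
            y = _ols_residuals(y0, X[accepted_idx].T)
        else:
            y = y0.copy()
        t_all, slope_all = _all_snp_stats(Xc, sxx, y)
        taken = np.zeros(gm.n_snps, dtype=bool)
        taken[accepted_idx] = True
        t_mask = np.where(taken, -1.0, t_all)

        candidates = []  # (snp_index, |t|, slope)
        for c in chrom_labels:
            idx = chrom_idx[c]
            tc = t_mask[idx]
            best = tc.max()
            if best <= 0:
                continue
            ties = idx[tc >= best]  # positions increase along idx
            candidates.append((int(ties[0]), float(best), float(slope_all[ties[0]])))
        if not candidates:
            break

        # permutation null: chromosome-best |t| under shuffled working phenotype
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
        perms = perms - perms.mean(axis=0, keepdims=True)
        sxy = Xc @ perms  # (n_snps, n_perm)
        syy = np.einsum("ij,ij->j", perms, perms)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(np.outer(np.where(sxx > 0, sxx, np.inf), syy))
            rho = sxy / denom
            rho = np.clip(rho, -1.0, 1.0)
            t_perm = np.abs(rho) * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        chrom_best = np.stack([t_perm[chrom_idx[c]].max(axis=0) for c in chrom_labels])
        # chrom_best: (n_chrom, n_perm)

        stats_sorted = sorted((s for _, s, _ in candidates), reverse=True)
        accepted_this_round = []
        for snp_i, s, slope in candidates:
            exceed = float((chrom_best >= s).sum()) / n_perm
            n_real = sum(1 for v in stats_sorted if v >= s)
            q = exceed / n_real
            if q <= fdr:
                dof = n - 2
                p = 2.0 * stats.t.sf(s, dof) if np.isfinite(s) else 0.0
                accepted_this_round.append(
                    QTLRecord(
                        snp_id=str(gm.snp_ids[snp_i]),
                        chromosome=str(gm.chromosomes[snp_i]),
                        position=int(gm.positions[snp_i]),
                        trait=trait,
                        environment=environment,
                        round=rnd,
                        stat=s,
                        p=float(p),
                        snp_index=snp_i,
                    )
                )
        if not accepted_this_round:
            break
        # deterministic order: smaller p (larger stat), chromosome map order, position
        order = {c: k for k, c in enumerate(chrom_labels)}
        accepted_this_round.sort(key=lambda q: (-q.stat, order[q.chromosome], q.position))
        accepted.extend(accepted_this_round)
        accepted_idx.extend(q.snp_index for q in accepted_this_round)

    return accepted


def variance_explained(snp_indices: Sequence[int], phenotype, gm: GenotypeMatrix) -> float:
    """R^2 of the joint OLS of the phenotype on the given SNP codes."""
    idx = np.asarray(snp_indices, dtype=int)
    if len(idx) == 0:
        raise InputDataError("variance_explained requires a non-empty SNP set")
    y = np.asarray(phenotype, dtype=float)
    X = gm.imputed()[idx].T
    resid = _ols_residuals(y, X)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise UndefinedStatisticError("phenotype is constant; R^2 undefined")
    return 1.0 - float(resid @ resid) / sst


def prune_to_top_k(
    qtls: Sequence[QTLRecord], phenotype, gm: GenotypeMatrix, k: int = 36
) -> list[QTLRecord]:
    """Greedy backward elimination to the k QTLs jointly explaining the most.

    Each step removes the QTL whose removal reduces the joint R^2 least
    (ties broken toward the earlier list position), recomputing R^2 from
    scratch each step.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    current = list(qtls)
    if len(current) < k:
        raise InputDataError(f"cannot prune {len(current)} QTLs to k={k}")
    y = np.asarray(phenotype, dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise UndefinedStatisticError("phenotype is constant; R^2 undefined")
    # Gram-matrix bookkeeping: R^2 of any subset needs only the (k+1) x (k+1)
    # normal equations, not a fresh n x k least squares per candidate removal.
    X = gm.imputed()[[q.snp_index for q in current]].T
    A = np.column_stack([np.ones(len(y)), X])
    G = A.T @ A
    b = A.T @ y
    syy = float(y @ y)

    def r2_of(cols: list[int]) -> float:
        sel = [0] + [c + 1 for c in cols]
        Gs = G[np.ix_(sel, sel)]
        bs = b[sel]
        beta, *_ = np.linalg.lstsq(Gs, bs, rcond=None)
        sse = syy - float(bs @ beta)
        return 1.0 - max(sse, 0.0) / sst

    alive = list(range(len(current)))
    while len(alive) > k:
        best_r2 = -np.inf
        drop = 0
        for i in range(len(alive)):
            r2 = r2_of(alive[:i] + alive[i + 1 :])
            if r2 > best_r2 + 1e-15:
                best_r2 = r2
                drop = i
        alive.pop(drop)
    return [current[i] for i in alive]


def random_snp_baseline(
    phenotype,
    gm: GenotypeMatrix,
    observed_r2: float,
    k: int = 36,
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of R^2 from random k-SNP sets and the empirical p.

    empirical_p = (1 + #{samples with R^2 >= observed}) / (n_samples + 1).
    """
    if k > gm.n_snps:
        raise InputDataError(f"k={k} exceeds the {gm.n_snps} available SNPs")
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_samples)
    for s in range(n_samples):
        idx = rng.choice(gm.n_snps, size=k, replace=False)
        r2s[s] = variance_explained(idx, phenotype, gm)
    p = (1.0 + float((r2s >= observed_r2).sum())) / (n_samples + 1.0)
    return r2s, p


def _flag_collinear(X: np.ndarray) -> np.ndarray:
    """Mark columns of X that are (numerically) linear combinations of the
    remaining columns plus an intercept."""
    k = X.shape[1]
    flags = np.zeros(k, dtype=bool)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) == k + 1:
        return flags
    for j in range(k):
        others = np.delete(X, j, axis=1)
        resid = _ols_residuals(X[:, j], others)
        denom = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if denom == 0 or float(resid @ resid) / denom < 1e-10:
            flags[j] = True
    return flags


def qtl_effects(
    qtls: Sequence[QTLRecord], phenotype_r, phenotype_K, gm: GenotypeMatrix
) -> list[QTLRecord]:
    """Joint-regression effects of each QTL on r and on K, with pleiotropy class.

    Both traits are regressed on all QTL codes simultaneously; each QTL's
    coefficients are its effects.  Same signs (both nonzero) = concordant;
    opposite signs = antagonistic; a zero or collinearity-flagged
    coefficient = null.
    """
    qtls = list(qtls)
    if not qtls:
        return []
    yr = np.asarray(phenotype_r, dtype=float)
    yK = np.asarray(phenotype_K, dtype=float)
    idx = [q.snp_index for q in qtls]
    X = gm.imputed()[idx].T
    bad = _flag_collinear(X)
    A = np.column_stack([np.ones(len(yr)), X])
    beta_r, *_ = np.linalg.lstsq(A, yr, rcond=None)
    beta_K, *_ = np.linalg.lstsq(A, yK, rcond=None)
    out = []
    for j, q in enumerate(qtls):
        er, eK = float(beta_r[j + 1]), float(beta_K[j + 1])
        if bad[j] or er == 0.0 or eK == 0.0:
            cls = "null"
        elif np.sign(er) == np.sign(eK):
            cls = "concordant"
        else:
            cls = "antagonistic"
        out.append(
            QTLRecord(
                snp_id=q.snp_id,
                chromosome=q.chromosome,
                position=q.position,
                trait=q.trait,
                environment=q.environment,
                round=q.round,
                stat=q.stat,
                p=q.p,
                effect_r=er,
                effect_K=eK,
                pleiotropy=cls,
                snp_index=q.snp_index,
            )
        )
    return out


def segment_enrichment(
    all_qtls: Sequence[QTLRecord],
    gm: GenotypeMatrix,
    segment_len: int = 3000,
    threshold: int = 4,
    n_null: int = 1000,
    seed: int = 0,
    set_sizes: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, float]:
    """Count pooled QTL instances in fixed genomic windows and the null
    expectation of the number of enriched windows.

    Chromosomes are tiled with half-open ``segment_len``-bp windows anchored
    at position 1.  The same SNP mapped in several trait x environment
    combinations counts once per combination.  A window with >= ``threshold``
    instances is enriched.  The null redraws each trait x environment's QTL
    set as distinct SNPs uniform on the mapping map (preserving SNP density)
    and reports the mean count of enriched windows over ``n_null`` replicates.
    """
    qtls = list(all_qtls)
    if not qtls:
        raise InputDataError("segment_enrichment requires at least one QTL")
    rng = np.random.default_rng(seed)

    def window_of(chrom: str, pos: int) -> tuple[str, int]:
        return chrom, ((pos - 1) // segment_len) * segment_len + 1

    counts: dict[tuple[str, int], int] = {}
    traits_in: dict[tuple[str, int], set] = {}
    for q in qtls:
        w = window_of(q.chromosome, q.position)
        counts[w] = counts.get(w, 0) + 1
        traits_in.setdefault(w, set()).add(q.trait)
    rows = [
        {
            "chromosome": c,
            "segment_start": s,
            "n_qtls": n,
            "enriched": n >= threshold,
            "has_r_and_K": len(traits_in[(c, s)]) >= 2,
        }
        for (c, s), n in sorted(counts.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
    ]
    observed = pd.DataFrame(rows)

    if set_sizes is None:
        sizes: dict[tuple[str, str], int] = {}
        for q in qtls:
            key = (q.trait, q.environment)
            sizes[key] = sizes.get(key, 0) + 1
        set_sizes = list(sizes.values())

    win_keys = [
        f"{c}:{((int(p) - 1) // segment_len)}"
        for c, p in zip(gm.chromosomes, gm.positions)
    ]
    uniq, inv = np.unique(np.array(win_keys), return_inverse=True)
    n_win = len(uniq)

    enriched_counts = np.empty(n_null)
    for b in range(n_null):
        tally = np.zeros(n_win, dtype=np.int64)
        for sz in set_sizes:
            draw = rng.choice(gm.n_snps, size=sz, replace=False)
            np.add.at(tally, inv[draw], 1)
        enriched_counts[b] = int((tally >= threshold).sum())
    return observed, float(enriched_counts.mean())


def representative_snp_effect(
    snp_index: int, gm: GenotypeMatrix, phenotype
) -> tuple[float, float]:
    """Homozygote-contrast effect of one SNP on a phenotype.

    effect = mean(phenotype | code 2) - mean(phenotype | code 0);
    SE = sqrt(s2^2/n2 + s0^2/n0).  Heterozygotes are excluded.  Either
    homozygote class with fewer than 2 members makes the contrast undefined.
    """
    y = np.asarray(phenotype, dtype=float)
    x = gm.codes[int(snp_index)]
    g0 = y[(x == 0) & np.isfinite(y)]
    g2 = y[(x == 2) & np.isfinite(y)]
    if len(g0) < 2 or len(g2) < 2:
        raise UndefinedStatisticError(
            f"need >= 2 genotypes per homozygote class, got {len(g0)} and {len(g2)}"
        )
    effect = float(g2.mean() - g0.mean())
    se = float(np.sqrt(g2.var(ddof=1) / len(g2) + g0.var(ddof=1) / len(g0)))
    return effect, se
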