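"""QTL mapping machinery: LD pruning, association, iterative mapping,
variance explained, backward pruning, random baselines, effects and
segment enrichment."""

import numpy as np
import pytest
from scipy import stats

from rkpleio.exceptions import ConfigurationError, InputDataError, UndefinedStatisticError
from rkpleio.qtl import (
    map_qtls,
    prune_complete_ld,
    prune_to_top_k,
    qtl_effects,
    random_snp_baseline,
    representative_snp_effect,
    segment_enrichment,
    snp_association,
    variance_explained,
)
from tests.conftest import tiny_matrix


# ------------------------------------------------------------------- pruning

def test_prune_identity_when_all_distinct(small_gm):
    # a simulated cross rarely has identical neighbours at 50 SNPs/chrom;
    # construct a guaranteed-distinct matrix instead
    rng = np.random.default_rng(0)
    codes = rng.integers(0, 3, size=(20, 30)).astype(float)
    while any(
        np.array_equal(codes[i], codes[i + 1]) for i in range(19)
    ):  # pragma: no cover
        codes = rng.integers(0, 3, size=(20, 30)).astype(float)
    gm = tiny_matrix(codes)
    assert prune_complete_ld(gm).n_snps == 20


def test_prune_keeps_middle_of_run():
    v = np.array([0, 1, 2, 1, 0, 1])
    codes = np.stack([v, v, v, v + 0.0 * 0 + (v == 0) * 0 + 1 * 0 + 0 * v, v * 0 + 1])
    codes[3] = [2, 1, 0, 1, 2, 1]  # break: row3 distinct
    gm = tiny_matrix(codes)
    out = prune_complete_ld(gm)
    # rows 0,1,2 identical -> keep middle (index 1); rows 3,4 distinct
    assert list(out.snp_ids) == ["s1", "s3", "s4"]


def test_prune_even_run_keeps_lower_middle():
    v = np.array([0.0, 1, 2, 0])
    codes = np.stack([v, v, v, v])
    out = prune_complete_ld(tiny_matrix(codes))
    assert list(out.snp_ids) == ["s1"]


def test_prune_respects_chromosome_boundaries():
    v = np.array([0.0, 1, 2, 0])
    codes = np.stack([v, v])
    gm = tiny_matrix(codes, chroms=["chr01", "chr02"])
    assert prune_complete_ld(gm).n_snps == 2


def test_prune_matches_duplicate_run_oracle(rng):
    n_snps, n_gen = 60, 25
    codes = rng.integers(0, 3, size=(n_snps, n_gen)).astype(float)
    # plant runs of duplicates
    for start, length in [(5, 3), (20, 4), (40, 2), (55, 5)]:
        for k in range(1, length):
            codes[start + k] = codes[start]
    chroms = ["chr01"] * 30 + ["chr02"] * 30
    gm = tiny_matrix(codes, chroms=chroms)
    out = prune_complete_ld(gm)

    # oracle: exhaustive grouping of consecutive duplicate rows per chromosome
    keep = []
    i = 0
    while i < n_snps:
        j = i
        while (
            j + 1 < n_snps
            and chroms[j + 1] == chroms[i]
            and (codes[j + 1] == codes[i]).all()
        ):
            j += 1
        keep.append((i + j) // 2)
        i = j + 1
    assert list(out.snp_ids) == [f"s{i}" for i in keep]


# --------------------------------------------------------------- association

def test_association_exact_and_constant(rng):
    codes = rng.integers(0, 3, 200).astype(float)
    t, p, slope = snp_association(codes.copy(), codes)
    assert p < 1e-100 and slope == pytest.approx(1.0)
    t0, p0, s0 = snp_association(np.full(200, 3.14), codes)
    assert s0 == pytest.approx(0.0, abs=1e-12)
    tm, pm, sm = snp_association(rng.normal(size=200), np.ones(200))
    assert (tm, pm, sm) == (0.0, 1.0, 0.0)


def test_association_matches_closed_form_ols():
    rng = np.random.default_rng(77)
    n = 500
    x = rng.integers(0, 3, n).astype(float)
    y = 0.5 * x + rng.normal(0, 1, n)
    t, p, slope = snp_association(y, x)
    # closed-form oracle
    xc = x - x.mean()
    yc = y - y.mean()
    bhat = (xc @ yc) / (xc @ xc)
    resid = yc - bhat * xc
    se = np.sqrt((resid @ resid) / (n - 2) / (xc @ xc))
    t_oracle = abs(bhat / se)
    assert t == pytest.approx(t_oracle, abs=1e-8)
    assert slope == pytest.approx(bhat, abs=1e-12)
    assert p == pytest.approx(2 * stats.t.sf(t_oracle, n - 2), rel=1e-10)


def test_association_missing_codes_imputed(rng):
    x = rng.integers(0, 3, 100).astype(float)
    y = x + rng.normal(0, 0.1, 100)
    x_miss = x.copy()
    x_miss[:5] = np.nan
    t, p, slope = snp_association(y, x_miss)
    assert p < 1e-10


# ------------------------------------------------------------------- mapping

def test_map_single_planted_qtl(small_gm, rng):
    snp = 125  # chromosome 3
    y = 1.0 * (small_gm.codes[snp] - 1) + rng.normal(0, 0.1, small_gm.n_genotypes)
    recs = map_qtls(y, small_gm, n_perm=100, seed=1)
    assert recs[0].snp_id == small_gm.snp_ids[snp]
    assert recs[0].round == 1


def test_map_two_qtls_same_chromosome_forward_selection(rng):
    """Two unlinked causal SNPs on one chromosome: the stronger is accepted
    first, the weaker only later from residuals (one per chromosome per
    round), matching a forward-selection oracle on the 2-SNP model."""
    n = 400
    codes = rng.integers(0, 3, size=(30, n)).astype(float)
    gm = tiny_matrix(codes)  # all on chr01
    y = 1.0 * codes[5] + 0.5 * codes[20] + rng.normal(0, 0.3, n)
    recs = map_qtls(y, gm, n_perm=100, seed=2, max_rounds=3)
    ids = [(r.snp_id, r.round) for r in recs]
    assert ("s5", 1) in ids
    later = [rd for s, rd in ids if s == "s20"]
    assert later and later[0] >= 2
    # forward-selection oracle: s5 has the larger marginal |t|
    t5 = snp_association(y, codes[5])[0]
    t20 = snp_association(y, codes[20])[0]
    assert t5 > t20


def test_map_bound_and_determinism(small_gm, rng):
    y = rng.normal(0, 1, small_gm.n_genotypes)
    for snp in range(0, small_gm.n_snps, 25):
        y = y + 0.4 * (small_gm.codes[snp] - 1)
    r1 = map_qtls(y, small_gm, n_perm=60, seed=9)
    r2 = map_qtls(y, small_gm, n_perm=60, seed=9)
    assert [(q.snp_id, q.round) for q in r1] == [(q.snp_id, q.round) for q in r2]
    n_chrom = len(set(small_gm.chromosomes))
    assert len(r1) <= n_chrom * 6
    assert len({q.snp_id for q in r1}) == len(r1)  # each SNP at most once


def test_map_configuration_errors(small_gm, rng):
    y = rng.normal(size=small_gm.n_genotypes)
    with pytest.raises(ConfigurationError):
        map_qtls(y, small_gm, n_perm=10)
    with pytest.raises(InputDataError):
        map_qtls(y[:-1], small_gm, n_perm=50)


def test_null_phenotype_accepts_little(small_gm, rng):
    y = rng.normal(size=small_gm.n_genotypes)
    recs = map_qtls(y, small_gm, n_perm=200, seed=3)
    # FDR 0.05 over ~6 candidates per round: expect few or no acceptances
    assert len(recs) <= 3


# --------------------------------------------------------- variance explained

def test_variance_explained_identity_and_monotone(small_gm, rng):
    snp = 42
    y = small_gm.codes[snp].astype(float)
    assert variance_explained([snp], y, small_gm) == pytest.approx(1.0)
    y2 = y + rng.normal(0, 1, len(y))
    a = variance_explained([snp], y2, small_gm)
    ab = variance_explained([snp, 100, 200], y2, small_gm)
    assert ab >= a - 1e-12


def test_variance_explained_null_expectation(rng):
    """Pure-noise phenotype on k SNPs: E[R^2] ~ k/(n-1), Monte-Carlo checked."""
    n, k = 150, 5
    codes = rng.integers(0, 3, size=(40, n)).astype(float)
    gm = tiny_matrix(codes)
    r2s = [
        variance_explained(rng.choice(40, k, replace=False), rng.normal(size=n), gm)
        for _ in range(300)
    ]
    expected = k / (n - 1)
    assert np.mean(r2s) == pytest.approx(expected, abs=3 * np.std(r2s) / np.sqrt(300) + 0.005)


def test_variance_explained_collinear_set(small_gm, rng):
    y = rng.normal(size=small_gm.n_genotypes)
    r2 = variance_explained([10, 10, 10], y, small_gm)  # duplicated column
    assert 0 <= r2 <= 1


# ------------------------------------------------------------------- pruning

def test_prune_to_top_k_drops_null_qtl_first(small_gm, rng):
    y = 1.0 * small_gm.codes[5] + 0.5 * small_gm.codes[80] + rng.normal(0, 0.2, small_gm.n_genotypes)
    recs = map_qtls(y, small_gm, n_perm=100, seed=4)
    idxs = {q.snp_index for q in recs}
    assert {5, 80} & idxs  # at least one causal SNP found
    if len(recs) > 2:
        top2 = prune_to_top_k(recs, y, small_gm, k=2)
        assert {q.snp_index for q in top2} <= idxs
        r2_full = variance_explained([q.snp_index for q in recs], y, small_gm)
        r2_top = variance_explained([q.snp_index for q in top2], y, small_gm)
        assert r2_top <= r2_full + 1e-12


def test_prune_to_top_k_matches_exhaustive_oracle(rng):
    n = 300
    codes = rng.integers(0, 3, size=(12, n)).astype(float)
    gm = tiny_matrix(codes)
    beta = np.array([1.0, 0.7, 0.5, 0.3, 0.2, 0.1])
    causal = [0, 2, 4, 6, 8, 10]
    y = sum(b * codes[c] for b, c in zip(beta, causal)) + rng.normal(0, 0.3, n)
    recs = map_qtls(y, gm, n_perm=100, seed=5, max_rounds=6)
    recs = [q for q in recs if q.snp_index in causal][:6]
    if len(recs) < 5:
        pytest.skip("mapping found fewer than 5 causal QTLs on this draw")
    k = len(recs) - 2

    # oracle: exhaustively evaluate every single-removal R^2 at each step
    working = list(recs)
    while len(working) > k:
        r2s = [
            variance_explained([q.snp_index for j, q in enumerate(working) if j != i], y, gm)
            for i in range(len(working))
        ]
        working.pop(int(np.argmax(r2s)))
    oracle_ids = [q.snp_id for q in working]
    pruned = prune_to_top_k(recs, y, gm, k=k)
    assert [q.snp_id for q in pruned] == oracle_ids


def test_prune_to_top_k_edge_cases(small_gm, rng):
    y = rng.normal(size=small_gm.n_genotypes)
    recs = map_qtls(1.0 * small_gm.codes[5] + y * 0.2, small_gm, n_perm=100, seed=6)
    assert prune_to_top_k(recs, y, small_gm, k=len(recs)) == recs
    with pytest.raises(ConfigurationError):
        prune_to_top_k(recs, y, small_gm, k=0)
    with pytest.raises(InputDataError):
        prune_to_top_k(recs, y, small_gm, k=len(recs) + 1)


# ------------------------------------------------------------------ baseline

def test_random_baseline_null_calibration(small_gm, rng):
    y = rng.normal(size=small_gm.n_genotypes)
    obs = variance_explained(rng.choice(small_gm.n_snps, 10, replace=False), y, small_gm)
    r2s, p = random_snp_baseline(y, small_gm, obs, k=10, n_samples=100, seed=7)
    lo, hi = np.quantile(r2s, [0.025, 0.975])
    assert lo <= obs <= hi
    assert p >= 1.0 / 101.0


def test_random_baseline_detects_shared_architecture(small_gm, rng):
    causal = rng.choice(small_gm.n_snps, 8, replace=False)
    g = sum(1.0 * (small_gm.codes[c] - 1) for c in causal)
    y_r = g + rng.normal(0, 0.5, small_gm.n_genotypes)
    y_K = g + rng.normal(0, 0.5, small_gm.n_genotypes)
    # r-mapped QTLs should explain K variance better than random sets
    recs = map_qtls(y_r, small_gm, n_perm=100, seed=8)
    obs = variance_explained([q.snp_index for q in recs], y_K, small_gm)
    _, p = random_snp_baseline(y_K, small_gm, obs, k=len(recs), n_samples=200, seed=9)
    assert p < 0.05


# -------------------------------------------------------------------- effects

def test_qtl_effects_sign_rules_and_simple_regression(small_gm, rng):
    snp = 33
    x = small_gm.codes[snp]
    y_r = 0.02 * x + rng.normal(0, 0.001, len(x))
    y_K = -1e5 * x + rng.normal(0, 1e3, len(x))
    recs = map_qtls(y_r, small_gm, n_perm=100, seed=10)
    one = [q for q in recs if q.snp_index == snp]
    assert one
    eff = qtl_effects(one, y_r, y_K, small_gm)
    assert eff[0].pleiotropy == "antagonistic"
    assert eff[0].effect_r > 0 > eff[0].effect_K
    # single-QTL joint regression equals cov/var
    xc = x - x.mean()
    assert eff[0].effect_r == pytest.approx(float(xc @ (y_r - y_r.mean())) / float(xc @ xc), rel=1e-9)

    y_K2 = 1e5 * x + rng.normal(0, 1e3, len(x))
    assert qtl_effects(one, y_r, y_K2, small_gm)[0].pleiotropy == "concordant"


def test_qtl_effects_collinear_flagged(rng):
    n = 100
    base = rng.integers(0, 3, n).astype(float)
    codes = np.stack([base, base, rng.integers(0, 3, n).astype(float)])
    gm = tiny_matrix(codes)
    y = base + rng.normal(0, 0.1, n)
    recs = map_qtls(y, gm, n_perm=50, seed=11, max_rounds=1)
    from rkpleio.qtl import QTLRecord

    fake = [
        QTLRecord("s0", "chr01", 100, "r", "e", 1, 5.0, 1e-4, snp_index=0),
        QTLRecord("s1", "chr01", 200, "r", "e", 1, 5.0, 1e-4, snp_index=1),
    ]
    eff = qtl_effects(fake, y, -y, gm)
    assert all(q.pleiotropy == "null" for q in eff)


# ---------------------------------------------------------------- enrichment

def test_segment_counts_single_hot_snp(small_gm):
    from rkpleio.qtl import QTLRecord

    qtls = [
        QTLRecord("s10", "chr01", 10_001, t, e, 1, 5.0, 1e-4, snp_index=10)
        for t in ("r", "K")
        for e in ("e1", "e2", "e3", "e4")
    ]
    seg, null_mean = segment_enrichment(qtls, small_gm, n_null=50, seed=1)
    assert len(seg) == 1
    assert seg.n_qtls.iloc[0] == 8
    assert bool(seg.enriched.iloc[0])
    assert bool(seg.has_r_and_K.iloc[0])
    assert seg.segment_start.iloc[0] == 9001  # window [9001, 12001) holds 10001


def test_segment_mean_count_arithmetic(small_gm):
    """Mean QTL count per window = instances / windows (the 648-over-4500
    bookkeeping of a full screen, checked on the small map)."""
    from rkpleio.qtl import QTLRecord

    rng = np.random.default_rng(3)
    picks = rng.choice(small_gm.n_snps, 40)
    qtls = [
        QTLRecord(
            str(small_gm.snp_ids[i]),
            str(small_gm.chromosomes[i]),
            int(small_gm.positions[i]),
            "r",
            f"e{j}",
            1,
            5.0,
            1e-4,
            snp_index=int(i),
        )
        for j, i in enumerate(picks)
    ]
    seg, _ = segment_enrichment(qtls, small_gm, segment_len=3000, n_null=20, seed=2)
    # windows tiling the small map: 50 SNPs x 1 kb spacing per chromosome
    span = 1 + (50 - 1) * 1000
    windows_per_chrom = int(np.ceil(span / 3000))
    n_windows = 6 * windows_per_chrom
    assert seg.n_qtls.sum() == 40
    assert 40 / n_windows == pytest.approx(0.392, abs=0.01)


def test_segment_null_matches_independent_placement_oracle(small_gm):
    from rkpleio.qtl import QTLRecord

    qtls = [
        QTLRecord("s0", "chr01", 1, "r", "e1", 1, 5.0, 1e-4, snp_index=0)
        for _ in range(2)
    ]
    sizes = [6, 6, 6]
    _, null_mean = segment_enrichment(
        qtls, small_gm, threshold=2, n_null=400, seed=5, set_sizes=sizes
    )
    # oracle: same sampling scheme, independent implementation and RNG
    rng = np.random.default_rng(987)
    win = [
        (str(c), (int(p) - 1) // 3000)
        for c, p in zip(small_gm.chromosomes, small_gm.positions)
    ]
    means = []
    for _ in range(400):
        tally = {}
        for sz in sizes:
            for i in rng.choice(small_gm.n_snps, sz, replace=False):
                tally[win[i]] = tally.get(win[i], 0) + 1
        means.append(sum(1 for v in tally.values() if v >= 2))
    oracle = np.mean(means)
    mc_sd = np.std(means) / np.sqrt(400)
    assert null_mean == pytest.approx(oracle, abs=6 * mc_sd + 0.05)


# ---------------------------------------------------- representative effects

def test_representative_effect_closed_forms(rng):
    n = 100
    codes = np.concatenate([np.zeros(n), np.full(n, 2.0)])
    gm = tiny_matrix(codes[None, :])
    y = np.concatenate([rng.normal(0.25, 0.05, n), rng.normal(0.30, 0.05, n)])
    effect, se = representative_snp_effect(0, gm, y)
    g0, g2 = y[:n], y[n:]
    assert effect == pytest.approx(g2.mean() - g0.mean(), rel=1e-12)
    assert se == pytest.approx(np.sqrt(g2.var(ddof=1) / n + g0.var(ddof=1) / n), rel=1e-12)
    # identical class values -> zero effect
    effect0, _ = representative_snp_effect(0, gm, np.concatenate([np.ones(n), np.ones(n)]))
    assert effect0 == 0.0


def test_representative_effect_additive_identity(small_gm, rng):
    beta = 0.3
    snp = 7
    y = beta * small_gm.codes[snp] + rng.normal(0, 0.05, small_gm.n_genotypes)
    effect, se = representative_snp_effect(snp, small_gm, y)
    assert effect == pytest.approx(2 * beta, abs=4 * se)


def test_representative_effect_undefined_class():
    gm = tiny_matrix(np.ones((1, 20)))  # all heterozygous
    with pytest.raises(UndefinedStatisticError):
        representative_snp_effect(0, gm, np.arange(20.0))
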