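"""Density computations, rank tests and the random-gene-set null."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from alusel.enrichment import (
    DensityRecord,
    group_density_comparison,
    mann_whitney_u,
    random_geneset_null,
    snp_density,
    two_sample_t,
)


def test_snp_density_basic():
    n, bp, d = snp_density([(0, 250)], [10, 20, 30, 40, 50])
    assert (n, bp, d) == (5, 250, 0.02)
    n, bp, d = snp_density([(0, 100)], [])
    assert d == 0.0
    _, _, d = snp_density([], [1, 2])
    assert math.isnan(d)


def test_density_invariant_under_region_split():
    snps = [5, 15, 25, 99]
    whole = snp_density([(0, 100)], snps)
    split = snp_density([(0, 30), (30, 100)], snps)
    assert whole == split


def test_mwu_exact_worked_example():
    u, p = mann_whitney_u([1, 2], [3, 4], mode="exact")
    assert u == 0
    assert p == pytest.approx(1 / 3)


def test_mwu_identical_samples_p_one():
    _, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
    assert p == 1.0


def test_mwu_exact_matches_enumeration_small_samples():
    """Exact mode equals brute-force enumeration for all size pairs with
    n_x + n_y <= 10 (distinct values, no ties)."""
    rng = np.random.default_rng(0)
    for nx in range(1, 6):
        for ny in range(1, 6):
            vals = rng.permutation(nx + ny) + rng.normal(0, 0.01, nx + ny)
            x, y = vals[:nx], vals[ny:] if False else vals[nx:]
            u, p = mann_whitney_u(x, y, mode="exact")
            # oracle: enumerate labelings directly
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            def ustat(ix):
                rx = ranks[list(ix)].sum()
                return rx - nx * (nx + 1) / 2
            us = [ustat(c) for c in combinations(range(nx + ny), nx)]
            us = np.array(us)
            p_or = 2 * min((us <= u + 1e-9).mean(), (us >= u - 1e-9).mean())
            assert p == pytest.approx(min(1.0, p_or))


def test_mwu_exact_vs_normal_agree():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 6)
    y = rng.normal(0.5, 1, 6)
    _, pe = mann_whitney_u(x, y, mode="exact")
    _, pn = mann_whitney_u(x, y, mode="normal")
    assert pe == pytest.approx(pn, abs=0.02)


def test_welch_t():
    t, p = two_sample_t([1, 2, 3], [1, 2, 3])
    assert t == 0 and p == 1.0
    # equal-variance case: t = (2.5-4.5)/sqrt(2*(5/3)/4) = -2.191
    t, p = two_sample_t([1, 2, 3, 4], [3, 4, 5, 6])
    assert t == pytest.approx(-2.191, abs=1e-3)
    t_ref = stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=False).statistic
    assert t == pytest.approx(float(t_ref), abs=1e-12)
    t, p = two_sample_t([0, 0, 0], [1, 1, 1])
    assert math.isinf(t) and p == 0.0


def _universe(rng, n=400):
    lengths = {f"u{i}": float(rng.lognormal(7, 0.5)) for i in range(n)}
    metric = {g: float(rng.poisson(l / 100)) for g, l in lengths.items()}
    return lengths, metric


def test_null_deterministic_and_self_consistent():
    rng = np.random.default_rng(1)
    lengths, metric = _universe(rng)
    test_set = {f"t{i}": float(rng.lognormal(7, 0.5)) for i in range(32)}
    metric.update({g: 5.0 for g in test_set})
    n1 = random_geneset_null(lengths, test_set, metric, n_iter=200, seed=7)
    n2 = random_geneset_null(lengths, test_set, metric, n_iter=200, seed=7)
    assert np.array_equal(n1.values, n2.values)
    assert n1.mean == pytest.approx(float(np.mean(n1.values)), abs=1e-12)
    assert n1.sd == pytest.approx(float(np.std(n1.values, ddof=1)), abs=1e-12)
    assert n1.exceeds_3sd == (n1.test_value > n1.mean + 3 * n1.sd)


def test_null_z_scaling():
    """A test set built to sit ~4 SD above the null is flagged."""
    rng = np.random.default_rng(2)
    lengths, metric = _universe(rng)
    test_set = {f"t{i}": float(rng.lognormal(7, 0.5)) for i in range(32)}
    null0 = random_geneset_null(
        lengths, test_set, {**metric, **{g: 0.0 for g in test_set}},
        n_iter=400, seed=3,
    )
    target = null0.mean + 4 * null0.sd
    per_gene = target / 32
    metric2 = {**metric, **{g: per_gene for g in test_set}}
    null = random_geneset_null(lengths, test_set, metric2, n_iter=400, seed=3)
    assert null.z == pytest.approx(4.0, abs=0.5)
    assert null.exceeds_3sd


def test_null_rejects_overlap_and_missing_metric():
    rng = np.random.default_rng(4)
    lengths, metric = _universe(rng, 100)
    overlap = {next(iter(lengths)): 100.0}
    with pytest.raises(ValueError, match="exclude"):
        random_geneset_null(lengths, overlap, metric, n_iter=10, seed=0)
    with pytest.raises(KeyError):
        random_geneset_null(lengths, {"new": 100.0}, metric, n_iter=10, seed=0)


def test_null_false_positive_rate_under_null_universe():
    """When the test set is drawn from the same distribution as the universe,
    the mean+3SD flag fires in <= 2% of replicates."""
    rng = np.random.default_rng(10)
    n_flagged = 0
    n_rep = 200
    lengths, metric = _universe(rng, 600)
    genes = sorted(lengths)
    for rep in range(n_rep):
        sub = np.random.default_rng(1000 + rep)
        chosen = sub.choice(len(genes), size=32, replace=False)
        test_genes = {genes[i] for i in chosen}
        uni = {g: lengths[g] for g in genes if g not in test_genes}
        tset = {g: lengths[g] for g in test_genes}
        null = random_geneset_null(uni, tset, metric, n_iter=150, seed=rep)
        n_flagged += int(null.exceeds_3sd)
    assert n_flagged / n_rep <= 0.02


def test_group_density_comparison_direction():
    rng = np.random.default_rng(5)
    recs = []
    for i in range(40):
        recs.append(DensityRecord(f"g{i}", "alu_mirna_target", 500,
                                  int(rng.poisson(20))))
        recs.append(DensityRecord(f"g{i}", "utr_nonalu_mirna_target", 500,
                                  int(rng.poisson(5))))
    table = group_density_comparison(recs, metrics=("density",))
    row = table.iloc[0]
    assert row["p"] < 0.05
    assert row["direction"] == "alu_mirna_target>utr_nonalu_mirna_target"


def test_group_density_identical_groups_p_high():
    recs = []
    for i in range(20):
        recs.append(DensityRecord(f"g{i}", "alu_mirna_target", 500, 10))
        recs.append(DensityRecord(f"g{i}", "utr_nonalu_mirna_target", 500, 10))
    table = group_density_comparison(recs, metrics=("density",))
    assert table.iloc[0]["p"] == pytest.approx(1.0)
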