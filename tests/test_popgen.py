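"""Population-genetic statistics: frequencies, F_ST, theta estimators,
Tajima's D, Fay-Wu's H, EHH/iHS, VCF input."""

import math

import numpy as np
import pytest

from alusel.popgen import (
    HaplotypePanel,
    TajimaConstants,
    allele_freq,
    daf,
    ehh,
    faywu_h,
    fst_wc_components,
    fst_wc_global,
    fst_wc_multilocus,
    fst_wc_pairwise,
    ihs_standardize,
    ihs_unstandardized,
    read_vcf,
    selection_scan,
    tajimas_d,
    window_sfs,
)
from alusel.simulate import PopSimConfig, simulate_balding_nichols, write_panel_tsv, write_vcf


def make_panel(cols, pops, polarized=None, positions=None):
    alle = np.asarray(cols, dtype=np.int8)
    S = alle.shape[1]
    return HaplotypePanel(
        positions=np.asarray(positions if positions is not None else np.arange(1, S + 1) * 10),
        alleles=alle,
        pops=np.asarray(pops),
        polarized=np.asarray(polarized if polarized is not None else [True] * S),
    )


FOUR_HAP = make_panel(
    [[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], ["P"] * 4
)


def test_allele_freq_and_daf():
    p = make_panel([[1], [1], [0], [0]], ["A"] * 4)
    assert allele_freq(p, 0, "A") == 0.5
    p0 = make_panel([[0], [0]], ["A"] * 2)
    assert daf(p0, 0, "A") == 0.0
    unpol = make_panel([[1], [0]], ["A"] * 2, polarized=[False])
    assert math.isnan(daf(unpol, 0, "A"))


def test_daf_missing_excluded():
    p = make_panel([[1], [-1], [0], [-1]], ["A"] * 4)
    assert allele_freq(p, 0, "A") == 0.5


def test_table1_ddaf_arithmetic():
    """ZNF500 rs921864: DAF CHB 0.737, YRI 0.045 -> dDAF 0.692."""
    assert 0.737 - 0.045 == pytest.approx(0.692)


@pytest.mark.parametrize(
    "freqs,sizes,expected",
    [
        ([1.0, 0.0], [10, 10], 1.0),
        ([0.2, 0.8], [10, 10], 0.47709),
    ],
)
def test_wc_theta_worked_examples(freqs, sizes, expected):
    assert fst_wc_components(freqs, sizes).theta == pytest.approx(expected, abs=1e-4)


def test_wc_monomorphic_undefined_not_zero():
    assert math.isnan(fst_wc_components([0.0, 0.0], [10, 10]).theta)
    assert math.isnan(fst_wc_components([1.0, 1.0, 1.0], [10, 10, 10]).theta)


def test_wc_global_two_pops_equals_pairwise():
    rng = np.random.default_rng(1)
    alle = rng.integers(0, 2, (30, 20)).astype(np.int8)
    p = make_panel(alle, ["A"] * 14 + ["B"] * 16)
    for s in range(20):
        g = fst_wc_global(p, s, ["A", "B"])
        pw = fst_wc_pairwise(p, s, "A", "B")
        if math.isnan(g):
            assert math.isnan(pw)
        else:
            assert g == pytest.approx(pw, abs=1e-12)


def test_theta_estimators_vs_pairwise_oracle():
    """theta_pi from the window matches a naive O(n^2 S) pairwise-difference
    count, and theta_w matches S/a1, on random 20x50 panels."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        alle = (rng.random((20, 50)) < rng.uniform(0.05, 0.5, 50)).astype(np.int8)
        p = make_panel(alle, ["A"] * 20)
        sfs = window_sfs(p, "A", 250, 10_000)
        n = 20
        # brute force mean pairwise differences over segregating sites
        pi = 0.0
        seg = 0
        for s in range(50):
            col = alle[:, s]
            i = col.sum()
            if 0 < i < n:
                seg += 1
                diffs = sum(
                    int(col[a] != col[b]) for a in range(n) for b in range(a + 1, n)
                )
                pi += diffs / (n * (n - 1) / 2)
        a1 = sum(1 / k for k in range(1, n))
        assert sfs.theta_pi == pytest.approx(pi, abs=1e-10)
        assert sfs.theta_w == pytest.approx(seg / a1, abs=1e-10)


def test_window_sfs_worked_examples():
    p2 = make_panel([[1], [1], [0], [0]], ["A"] * 4)
    sfs = window_sfs(p2, "A", 10, 100)
    assert sfs.theta_pi == pytest.approx(2 * 2 * 2 / 12)
    assert sfs.theta_h == pytest.approx(sfs.theta_pi)  # i=2, n=4: contribution to H is 0
    p3 = make_panel([[1], [1], [1], [0]], ["A"] * 4)
    sfs3 = window_sfs(p3, "A", 10, 100)
    assert sfs3.theta_pi == pytest.approx(0.5)
    assert sfs3.theta_h == pytest.approx(1.5)


def test_window_sfs_empty_window():
    sfs = window_sfs(FOUR_HAP, "P", 10_000, 10)
    assert sfs.S == 0 and sfs.theta_pi == 0 and sfs.theta_h == 0


def test_tajima_constants_and_d():
    k = TajimaConstants.for_n(4)
    assert k.a1 == pytest.approx(1 + 0.5 + 1 / 3)
    sfs = window_sfs(FOUR_HAP, "P", 20, 1000)
    assert tajimas_d(sfs) == pytest.approx(0.1677, abs=2e-3)


def test_tajima_d_undefined_when_no_segregating_sites():
    p = make_panel([[0], [0], [0], [0]], ["P"] * 4)
    sfs = window_sfs(p, "P", 10, 100)
    assert math.isnan(tajimas_d(sfs))


def test_faywu_h_worked_examples():
    sfs = window_sfs(FOUR_HAP, "P", 20, 1000)
    assert faywu_h(sfs) == pytest.approx(-2 / 3, abs=1e-9)
    # singletons only -> H > 0
    p = make_panel([[1, 0], [0, 1], [0, 0], [0, 0]], ["P"] * 4)
    assert faywu_h(window_sfs(p, "P", 10, 1000)) > 0
    # i in {1,3}, one site each: pi = 6/12 + 6/12 = 1, H-est = (2+18)/12 = 5/3
    p2 = make_panel([[1, 1], [0, 1], [0, 1], [0, 0]], ["P"] * 4)
    sfs2 = window_sfs(p2, "P", 10, 1000)
    assert sfs2.theta_pi == pytest.approx(1.0)
    assert sfs2.theta_h == pytest.approx(5 / 3)
    assert faywu_h(sfs2) == pytest.approx(-2 / 3)


def test_ehh_definition_and_monotonicity():
    rng = np.random.default_rng(3)
    alle = (rng.random((30, 40)) < 0.3).astype(np.int8)
    alle[:, 20] = np.array([1] * 15 + [0] * 15)  # balanced core
    p = make_panel(alle, ["A"] * 30)
    for cls in (0, 1):
        for d in (+1, -1):
            c = ehh(p, "A", 20, cls, d, site_maf_min=0.0)
            assert c.ehh[0] == 1.0
            assert np.all(np.diff(c.ehh) <= 1e-12)
            assert c.ihh >= 0


def test_ehh_small_class_undefined():
    p = make_panel([[1, 0], [0, 0], [0, 1], [0, 0]], ["A"] * 4)
    with pytest.raises(ValueError):
        ehh(p, "A", 0, 1)  # single derived haplotype


def test_ihs_symmetric_classes_give_zero():
    """Two internally identical allele classes: iHH_A = iHH_D, u = 0."""
    block = np.zeros((20, 11), dtype=np.int8)
    block[:10, 5] = 1          # derived class
    block[:10, :] [:, [0, 10]] = 1  # shared flanking pattern inside class
    p = make_panel(block, ["A"] * 20)
    u = ihs_unstandardized(p, "A", 5, maf_min=0.05)
    assert u == pytest.approx(0.0, abs=1e-12)


def test_ihs_sign_when_derived_class_identical():
    """Derived class identical, ancestral class split at flanking sites ->
    iHH_A < iHH_D -> u < 0."""
    rng = np.random.default_rng(4)
    alle = np.zeros((40, 21), dtype=np.int8)
    alle[:20, 10] = 1  # derived class: 20 identical haplotypes
    # ancestral class: scrambled flanks
    alle[20:, :10] = (rng.random((20, 10)) < 0.5).astype(np.int8)
    alle[20:, 11:] = (rng.random((20, 10)) < 0.5).astype(np.int8)
    p = make_panel(alle, ["A"] * 40)
    u = ihs_unstandardized(p, "A", 10, maf_min=0.05)
    assert u < 0


def test_ihs_standardize_bins():
    rng = np.random.default_rng(5)
    d = rng.uniform(0.05, 0.95, 200)
    u = 2 * d + rng.normal(0, 0.1, 200)  # frequency-dependent mean
    z = ihs_standardize(u, d, n_bins=10)
    ok = np.isfinite(z)
    assert ok.sum() == 200
    assert abs(np.nanmean(z)) < 0.1
    # all-identical u in a bin -> unscored
    z2 = ihs_standardize(np.ones(10), np.linspace(0.1, 0.12, 10), n_bins=1)
    assert np.all(np.isnan(z2))


def test_ihh_invariant_under_relabeling():
    rng = np.random.default_rng(6)
    alle = (rng.random((24, 30)) < 0.4).astype(np.int8)
    alle[:, 15] = np.array([1] * 12 + [0] * 12)
    p = make_panel(alle, ["A"] * 24)
    u1 = ihs_unstandardized(p, "A", 15)
    perm = rng.permutation(24)
    p2 = make_panel(alle[perm], ["A"] * 24)
    u2 = ihs_unstandardized(p2, "A", 15)
    assert u1 == pytest.approx(u2, abs=1e-12)


def test_balding_nichols_f_recovery():
    """Multi-locus WC theta recovers the Balding-Nichols F parameter."""
    for F in (0.1, 0.3):
        panel = simulate_balding_nichols(
            PopSimConfig(F=F, diploids_per_pop=100, n_snps=500, seed=1)
        )
        theta = fst_wc_multilocus(panel)
        assert theta == pytest.approx(F, abs=0.03)


def test_read_vcf_roundtrip(tmp_path):
    panel = simulate_balding_nichols(
        PopSimConfig(F=0.2, diploids_per_pop=5, n_snps=20, seed=3)
    )
    vcf = tmp_path / "p.vcf"
    tsv = tmp_path / "p.tsv"
    write_vcf(panel, str(vcf))
    write_panel_tsv(panel, str(tsv))
    back = read_vcf(str(vcf), str(tsv))
    assert np.array_equal(back.alleles, panel.alleles)
    assert np.array_equal(back.positions, panel.positions)
    assert list(back.pops) == list(panel.pops)
    assert back.polarized.all()


def test_read_vcf_polarity_swap(tmp_path):
    vcf = tmp_path / "x.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "1\t100\trs1\tA\tG\t.\tPASS\tAA=G\tGT\t0|0\t1|0\n"   # AA=ALT: swap
        "1\t200\trs2\tA\tG\t.\tPASS\tAA=N\tGT\t0|1\t1|1\n"   # unpolarized
    )
    tsv = tmp_path / "p.tsv"
    tsv.write_text("s1\tCEU\ns2\tCEU\n")
    panel = read_vcf(str(vcf), str(tsv))
    # site 0: REF homozygotes are derived after the swap
    assert list(panel.alleles[:, 0]) == [1, 1, 0, 1]
    assert panel.polarized[0] and not panel.polarized[1]
    assert len(panel.pops) == 4


def test_read_vcf_sample_missing_from_panel(tmp_path):
    vcf = tmp_path / "x.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\n"
    )
    tsv = tmp_path / "p.tsv"
    tsv.write_text("other\tCEU\n")
    with pytest.raises(ValueError, match="absent"):
        read_vcf(str(vcf), str(tsv))


def test_selection_scan_assembles_records():
    panel = simulate_balding_nichols(
        PopSimConfig(F=0.3, diploids_per_pop=30, n_snps=60, seed=9)
    )
    recs = selection_scan(panel, [0, 1, 2], {0: "gA", 1: "gB", 2: "gA"},
                          window_bp=5000, n_ihs_bins=5)
    assert len(recs) == 3
    r = recs[0]
    assert set(r.fst_pairwise) == {"YRI_CHB", "YRI_CEU", "CEU_CHB"}
    assert set(r.daf) == {"CEU", "CHB", "YRI"}
    for key, v in r.ddaf.items():
        a, b = key.split("_")
        assert v == pytest.approx(r.daf[a] - r.daf[b])
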