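"""Selection-scan statistics from phased, ancestral-polarized genotypes.

Implements, per SNP or per window: derived allele frequencies and their
between-population differences (DAF, dDAF), the Weir–Cockerham F_ST variance
component estimator (pairwise and global, haploid allele-level by default
with the diploid 1984 estimator as an option), the window estimators
theta_pi / theta_W / theta_H, Tajima's D, unnormalized Fay–Wu's H, extended
haplotype homozygosity (EHH) and the standardized integrated haplotype score
(iHS).

Conventions
-----------
Alleles are coded 0 = ancestral, 1 = derived, -1 = missing.  Sites whose
ancestral state is unknown are carried unpolarized (REF coded 0) and are
used for F_ST but excluded from DAF, theta_H, Fay–Wu's H and iHS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HaplotypePanel",
    "FstComponents",
    "SFSWindow",
    "TajimaConstants",
    "EhhCurve",
    "SelectionRecord",
    "allele_freq",
    "daf",
    "ddaf",
    "fst_wc_components",
    "fst_wc_pairwise",
    "fst_wc_global",
    "window_sfs",
    "tajimas_d",
    "faywu_h",
    "ehh",
    "ihs_unstandardized",
    "ihs_standardize",
    "read_vcf",
    "selection_scan",
    "records_to_dataframe",
]

POPULATIONS = ("CEU", "CHB", "YRI")
PAIRS = (("YRI", "CHB"), ("YRI", "CEU"), ("CEU", "CHB"))


@dataclass
class HaplotypePanel:
    """Phased haplotypes: ``alleles[h, s]`` for haplotype h at site s."""

    positions: np.ndarray          # (S,) int, strictly increasing
    alleles: np.ndarray            # (H, S) int8 in {0, 1, -1}
    pops: np.ndarray               # (H,) population label per haplotype
    polarized: np.ndarray          # (S,) bool
    snp_ids: list[str] | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.pops = np.asarray(self.pops)
        self.polarized = np.asarray(self.polarized, dtype=bool)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.shape != (len(self.pops), len(self.positions)):
            raise ValueError("alleles shape inconsistent with positions/pops")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def pop_index(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.pops == pop)
        if idx.size == 0:
            raise KeyError(f"no haplotypes for population {pop!r}")
        return idx

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pops:
            if p not in seen:
                seen.append(p)
        return seen


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def allele_freq(panel: HaplotypePanel, site: int, pop: str) -> float:
    """Frequency of the 1-coded allele among non-missing haplotypes of pop."""
    col = panel.alleles[panel.pop_index(pop), site]
    ok = col >= 0
    if not ok.any():
        return math.nan
    return float(col[ok].mean())


def daf(panel: HaplotypePanel, site: int, pop: str) -> float:
    """Derived allele frequency; NaN when the site is unpolarized."""
    if not panel.polarized[site]:
        return math.nan
    return allele_freq(panel, site, pop)


def ddaf(panel: HaplotypePanel, site: int, pop_a: str, pop_b: str) -> float:
    return daf(panel, site, pop_a) - daf(panel, site, pop_b)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstComponents:
    a: float
    b: float
    n_bar: float
    n_c: float
    p_bar: float
    s2: float

    @property
    def theta(self) -> float:
        tot = self.a + self.b
        if tot == 0 or math.isnan(tot):
            return math.nan
        return self.a / tot


def fst_wc_components(
    freqs: Sequence[float], sizes: Sequence[float]
) -> FstComponents:
    """Haploid (allele-level) Weir–Cockerham variance components.

    ``freqs``/``sizes`` are per-population allele frequencies and haplotype
    counts.  Monomorphic sites (p_bar in {0, 1}) yield theta = NaN.
    """
    p = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    r = len(p)
    if r < 2 or np.any(n < 2):
        return FstComponents(math.nan, math.nan, math.nan, math.nan, math.nan, math.nan)
    n_bar = n.sum() / r
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
    b = n_bar / (n_bar - 1) * inner
    a = n_bar / n_c * (s2 - inner / (n_bar - 1))
    if p_bar in (0.0, 1.0):
        return FstComponents(math.nan, math.nan, n_bar, n_c, p_bar, s2)
    return FstComponents(a, b, n_bar, n_c, p_bar, s2)


def _pop_freq_size(panel: HaplotypePanel, site: int, pop: str) -> tuple[float, int]:
    col = panel.alleles[panel.pop_index(pop), site]
    ok = col >= 0
    return (float(col[ok].mean()) if ok.any() else math.nan, int(ok.sum()))


def fst_wc_pairwise(panel: HaplotypePanel, site: int, pop_a: str, pop_b: str) -> float:
    fa, na = _pop_freq_size(panel, site, pop_a)
    fb, nb = _pop_freq_size(panel, site, pop_b)
    return fst_wc_components([fa, fb], [na, nb]).theta


def fst_wc_global(
    panel: HaplotypePanel, site: int, pops: Sequence[str] | None = None
) -> float:
    pops = list(pops) if pops is not None else panel.populations()
    fs, ns = zip(*(_pop_freq_size(panel, site, p) for p in pops))
    return fst_wc_components(fs, ns).theta


def fst_wc_multilocus(
    panel: HaplotypePanel, sites: Sequence[int] | None = None,
    pops: Sequence[str] | None = None,
) -> float:
    """Multi-locus Weir–Cockerham theta: sum(a) / sum(a + b) over sites.

    The per-SNP ratio a/(a+b) is not a consistent estimator of the
    differentiation parameter when averaged over loci (Jensen bias); summing
    the variance components before taking the ratio is the standard
    multi-locus form and recovers the simulated F.
    """
    pops = list(pops) if pops is not None else panel.populations()
    sites = range(panel.n_sites) if sites is None else sites
    num = den = 0.0
    for s in sites:
        fs, ns = zip(*(_pop_freq_size(panel, s, p) for p in pops))
        comp = fst_wc_components(fs, ns)
        if not math.isnan(comp.a):
            num += comp.a
            den += comp.a + comp.b
    return num / den if den > 0 else math.nan


def fst_wc_diploid(
    freqs: Sequence[float], het_freqs: Sequence[float], sizes: Sequence[float]
) -> float:
    """Diploid Weir–Cockerham (1984) theta with the heterozygosity term.

    ``sizes`` are diploid sample sizes, ``het_freqs`` observed heterozygote
    proportions.  Offered for unphased genotype data; the haploid estimator
    above is the package default on phased haplotypes.
    """
    p = np.asarray(freqs, dtype=float)
    h = np.asarray(het_freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    r = len(p)
    n_bar = n.sum() / r
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    pq = p_bar * (1 - p_bar)
    a = n_bar / n_c * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = n_bar / (n_bar - 1) * (
        pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    tot = a + b + c
    if tot == 0 or p_bar in (0.0, 1.0):
        return math.nan
    return a / tot


# ---------------------------------------------------------------------------
# Window SFS estimators, Tajima's D, Fay-Wu's H
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SFSWindow:
    """Per-window diversity estimators for one population.

    theta_pi and theta_w are computed over all segregating sites in the
    window; theta_h and theta_pi_polarized over the polarized subset only
    (the unpolarized SFS cannot be folded onto derived-allele counts).
    """

    n: int
    S: int
    theta_pi: float
    theta_w: float
    theta_h: float
    theta_pi_polarized: float
    s_polarized: int
    window_span: tuple[int, int]


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / k**power for k in range(1, n))


def window_sfs(
    panel: HaplotypePanel,
    pop: str,
    center_bp: int,
    window_bp: int,
    max_missing: float = 0.1,
) -> SFSWindow:
    """Site-frequency-spectrum estimators in [center - w/2, center + w/2).

    Sites with more than ``max_missing`` missing haplotypes in the
    population are dropped from the window.
    """
    idx = panel.pop_index(pop)
    if idx.size == 0:
        raise ValueError(f"no haplotypes in population {pop}")
    lo, hi = center_bp - window_bp // 2, center_bp + window_bp // 2
    in_win = (panel.positions >= lo) & (panel.positions < hi)
    sub = panel.alleles[np.ix_(idx, np.flatnonzero(in_win))]
    pol = panel.polarized[in_win]
    pi = w_s = th = pi_pol = 0.0
    s_all = s_pol = 0
    n_hap = idx.size
    for j in range(sub.shape[1]):
        col = sub[:, j]
        ok = col >= 0
        n = int(ok.sum())
        if n < 2 or (n_hap - n) > max_missing * n_hap:
            continue
        i = int(col[ok].sum())
        if i == 0 or i == n:
            continue
        contrib_pi = 2.0 * i * (n - i) / (n * (n - 1))
        pi += contrib_pi
        s_all += 1
        w_s += 1.0 / _harmonic(n)
        if pol[j]:
            th += 2.0 * i * i / (n * (n - 1))
            pi_pol += contrib_pi
            s_pol += 1
    return SFSWindow(
        n=n_hap, S=s_all, theta_pi=pi, theta_w=w_s, theta_h=th,
        theta_pi_polarized=pi_pol, s_polarized=s_pol, window_span=(lo, hi),
    )


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise ValueError("Tajima's D requires n >= 4")
        a1 = _harmonic(n)
        a2 = _harmonic(n, 2)
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(sfs: SFSWindow) -> float:
    """Tajima's D; NaN (not 0) when the window has no segregating sites."""
    if sfs.S < 1:
        return math.nan
    k = TajimaConstants.for_n(sfs.n)
    var = k.e1 * sfs.S + k.e2 * sfs.S * (sfs.S - 1)
    if var <= 0:
        return math.nan
    return (sfs.theta_pi - sfs.theta_w) / math.sqrt(var)


def faywu_h(sfs: SFSWindow) -> float:
    """Unnormalized Fay–Wu's H = theta_pi - theta_H over polarized sites.

    Strongly negative values mark an excess of high-frequency derived
    alleles, the footprint of a recent sweep.  Summed (not averaged) over the
    window, so dense windows give large magnitudes.
    """
    if sfs.s_polarized < 1:
        return math.nan
    return sfs.theta_pi_polarized - sfs.theta_h


# ---------------------------------------------------------------------------
# EHH and iHS
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    core_index: int
    allele_class: int                      # 0 ancestral, 1 derived
    positions: np.ndarray                  # bp, ordered outward from core
    ehh: np.ndarray                        # EHH at each position; [0] is core
    ihh: float
    edge_truncated: bool


def _ehh_one_direction(
    alleles: np.ndarray,
    positions: np.ndarray,
    haps: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
    informative: np.ndarray | None = None,
) -> tuple[list[int], list[float], bool]:
    """Walk outward from core refining the haplotype partition.

    ``informative`` optionally masks the sites used to distinguish
    haplotypes (rare variants are conventionally excluded, as in
    array-ascertained haplotype scans).
    """
    c = haps.size
    denom = c * (c - 1) / 2.0
    group = np.zeros(c, dtype=np.int64)
    steps_since_compact = 0
    pos_out = [int(positions[core])]
    ehh_out = [1.0]
    j = core + step
    truncated = True
    while 0 <= j < alleles.shape[1]:
        if informative is not None and not informative[j]:
            j += step
            continue
        col = alleles[haps, j]
        # missing treated as a third allele: breaks homozygosity conservatively
        group = group * 3 + (col + 1)
        steps_since_compact += 1
        if steps_since_compact >= 32:  # compact ids before int64 overflow
            _, group = np.unique(group, return_inverse=True)
            steps_since_compact = 0
        _, counts = np.unique(group, return_counts=True)
        val = float((counts * (counts - 1) / 2.0).sum() / denom)
        pos_out.append(int(positions[j]))
        ehh_out.append(val)
        if val < cutoff:
            truncated = False
            break
        j += step
    return pos_out, ehh_out, truncated


def _informative_sites(
    panel: HaplotypePanel, pop: str, site_maf_min: float
) -> np.ndarray:
    """Sites common enough in the population to distinguish haplotypes.

    Haplotype-homozygosity scans are conventionally run on common-variant
    panels (genotyping-array ascertainment); rare variants, which are
    typically very young, are excluded from the EHH walk.
    """
    idx = panel.pop_index(pop)
    sub = panel.alleles[idx, :]
    ok = sub >= 0
    n = ok.sum(axis=0)
    cnt = np.where(ok, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, cnt / np.maximum(n, 1), np.nan)
    return (f >= site_maf_min) & (f <= 1 - site_maf_min)


def ehh(
    panel: HaplotypePanel,
    pop: str,
    core_site: int,
    allele_class: int,
    direction: int = +1,
    cutoff: float = 0.05,
    site_maf_min: float = 0.05,
    _informative: np.ndarray | None = None,
) -> EhhCurve:
    """EHH decay curve for one allele class, one direction (+1 right, -1 left).

    Only sites with population minor-allele frequency >= ``site_maf_min``
    refine the haplotype partition (set 0 to use every site).
    """
    idx = panel.pop_index(pop)
    col = panel.alleles[idx, core_site]
    haps = idx[col == allele_class]
    if haps.size < 2:
        raise ValueError("allele class with < 2 haplotypes has undefined EHH")
    informative = _informative
    if informative is None and site_maf_min > 0:
        informative = _informative_sites(panel, pop, site_maf_min)
    pos, vals, trunc = _ehh_one_direction(
        panel.alleles, panel.positions, haps, core_site, direction, cutoff,
        informative,
    )
    p = np.asarray(pos, dtype=float)
    v = np.asarray(vals, dtype=float)
    ihh = float(np.trapezoid(v[np.argsort(p)], np.sort(p)))
    return EhhCurve(core_site, allele_class, p, v, ihh, trunc)


def ihs_unstandardized(
    panel: HaplotypePanel,
    pop: str,
    core_site: int,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    _informative: np.ndarray | None = None,
) -> float:
    """u = ln(iHH_ancestral / iHH_derived); NaN when ineligible.

    Requires a polarized core with derived frequency in
    [maf_min, 1 - maf_min] and >= 2 haplotypes per allele class.
    """
    if not panel.polarized[core_site]:
        return math.nan
    p = daf(panel, core_site, pop)
    if not (maf_min <= p <= 1 - maf_min):
        return math.nan
    informative = (
        _informative if _informative is not None
        else _informative_sites(panel, pop, maf_min)
    )
    try:
        curves = [
            ehh(panel, pop, core_site, cls, direction, cutoff,
                _informative=informative)
            for cls in (0, 1)
            for direction in (+1, -1)
        ]
    except ValueError:
        return math.nan
    ihh_a = curves[0].ihh + curves[1].ihh
    ihh_d = curves[2].ihh + curves[3].ihh
    if ihh_a <= 0 or ihh_d <= 0:
        return math.nan
    return math.log(ihh_a / ihh_d)


def ihs_standardize(
    u_values: np.ndarray, dafs: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Standardize unstandardized iHS within equal-count derived-frequency bins.

    Returns z-scores; entries in bins with < 2 scored SNPs, or with zero
    within-bin variance, are NaN (unscored).
    """
    u = np.asarray(u_values, dtype=float)
    d = np.asarray(dafs, dtype=float)
    z = np.full(u.shape, np.nan)
    ok = np.isfinite(u) & np.isfinite(d)
    if ok.sum() == 0:
        return z
    n_bins = max(1, min(n_bins, ok.sum()))
    edges = np.quantile(d[ok], np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.digitize(d, edges) - 1
    for b in range(n_bins):
        members = ok & (which == b)
        if members.sum() < 2:
            continue
        mu, sd = u[members].mean(), u[members].std(ddof=1)
        if sd == 0:
            continue
        z[members] = (u[members] - mu) / sd
    return z


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_panel_tsv(path: str) -> dict[str, str]:
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            if sample.lower() == "sample":
                continue
            pop_of[sample] = pop
    return pop_of


def read_vcf(
    vcf_path: str, panel_tsv: str, require_phased: bool = True
) -> HaplotypePanel:
    """Load phased biallelic SNPs with AA-polarity into a HaplotypePanel.

    The AA INFO tag gives the ancestral allele; when it matches ALT the
    coding is swapped so 1 = derived.  AA missing or matching neither allele
    leaves the site unpolarized (REF coded 0, usable for F_ST only).
    """
    from cyvcf2 import VCF

    pop_of = read_panel_tsv(panel_tsv)
    vcf = VCF(vcf_path)
    missing = [s for s in vcf.samples if s not in pop_of]
    if missing:
        raise ValueError(f"samples absent from panel TSV: {missing[:5]}")
    pops = np.repeat([pop_of[s] for s in vcf.samples], 2)
    positions, cols, polarized, ids = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        if require_phased and any(len(g) >= 3 and not g[2] for g in gts):
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS}; phased GT required"
            )
        hap = np.array([[g[0], g[1]] for g in gts], dtype=np.int8).reshape(-1)
        aa = var.INFO.get("AA")
        aa = aa.upper().strip(".|") if isinstance(aa, str) else None
        if aa == var.REF.upper():
            pol = True
        elif aa == var.ALT[0].upper():
            pol = True
            hap = np.where(hap >= 0, 1 - hap, hap).astype(np.int8)
        else:
            pol = False
        positions.append(var.POS - 1)
        cols.append(hap)
        polarized.append(pol)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not positions:
        raise ValueError(f"no usable biallelic SNPs in {vcf_path}")
    return HaplotypePanel(
        positions=np.asarray(positions),
        alleles=np.column_stack(cols),
        pops=pops,
        polarized=np.asarray(polarized),
        snp_ids=ids,
    )


# ---------------------------------------------------------------------------
# Per-SNP record assembly
# ---------------------------------------------------------------------------

@dataclass
class SelectionRecord:
    """All statistics for one SNP, mirroring one candidate-table row."""

    snp_id: str
    gene: str
    fst_global: float
    fst_pairwise: dict[str, float] = field(default_factory=dict)
    h: dict[str, float] = field(default_factory=dict)
    tajima_d: dict[str, float] = field(default_factory=dict)
    ihs: dict[str, float] = field(default_factory=dict)
    daf: dict[str, float] = field(default_factory=dict)

    @property
    def ddaf(self) -> dict[str, float]:
        out = {}
        for a, b in PAIRS:
            if a in self.daf and b in self.daf:
                out[f"{a}_{b}"] = self.daf[a] - self.daf[b]
        return out

    @property
    def max_ddaf(self) -> float:
        vals = [abs(v) for v in self.ddaf.values() if not math.isnan(v)]
        return max(vals) if vals else math.nan


def selection_scan(
    panel: HaplotypePanel,
    sites: Sequence[int],
    gene_of_site: Mapping[int, str] | None = None,
    window_bp: int = 30_000,
    n_ihs_bins: int = 20,
    pops: Sequence[str] | None = None,
) -> list[SelectionRecord]:
    """Compute the full statistics vector for each requested site.

    iHS is standardized across *all* eligible sites of the panel (not only
    the requested ones) so the empirical bin means/SDs are well estimated.
    """
    pops = list(pops) if pops is not None else panel.populations()
    gene_of_site = gene_of_site or {}
    # iHS over all panel sites, standardized per population
    z_by_pop: dict[str, np.ndarray] = {}
    for pop in pops:
        informative = _informative_sites(panel, pop, 0.05)
        u = np.array(
            [ihs_unstandardized(panel, pop, s, _informative=informative)
             for s in range(panel.n_sites)]
        )
        d = np.array([daf(panel, s, pop) for s in range(panel.n_sites)])
        z_by_pop[pop] = ihs_standardize(u, d, n_bins=n_ihs_bins)
    records = []
    for s in sites:
        snp_id = panel.snp_ids[s] if panel.snp_ids else f"site{s}"
        rec = SelectionRecord(
            snp_id=snp_id,
            gene=gene_of_site.get(s, ""),
            fst_global=fst_wc_global(panel, s, pops),
        )
        for a, b in PAIRS:
            if a in pops and b in pops:
                rec.fst_pairwise[f"{a}_{b}"] = fst_wc_pairwise(panel, s, a, b)
        for pop in pops:
            sfs = window_sfs(panel, pop, int(panel.positions[s]), window_bp)
            rec.h[pop] = faywu_h(sfs)
            rec.tajima_d[pop] = tajimas_d(sfs)
            rec.ihs[pop] = float(z_by_pop[pop][s])
            rec.daf[pop] = daf(panel, s, pop)
        records.append(rec)
    return records


def records_from_dataframe(df) -> list[SelectionRecord]:
    """Inverse of :func:`records_to_dataframe` (missing cells become NaN)."""
    def get(row, col):
        v = row.get(col)
        try:
            return float(v)
        except (TypeError, ValueError):
            return math.nan

    out = []
    for _, row in df.iterrows():
        out.append(
            SelectionRecord(
                snp_id=str(row.get("snp", "")),
                gene=str(row.get("gene", "")),
                fst_global=get(row, "fst_global"),
                fst_pairwise={
                    k: get(row, f"fst_{k.lower()}")
                    for k in ("YRI_CHB", "YRI_CEU", "CEU_CHB")
                },
                h={p: get(row, f"h_{p.lower()}") for p in POPULATIONS},
                tajima_d={p: get(row, f"d_{p.lower()}") for p in POPULATIONS},
                ihs={p: get(row, f"ihs_{p.lower()}") for p in POPULATIONS},
                daf={p: get(row, f"daf_{p.lower()}") for p in POPULATIONS},
            )
        )
    return out


def records_to_dataframe(records: Sequence[SelectionRecord]):
    """Flatten records into the candidate-table column layout."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"snp": r.snp_id, "gene": r.gene, "fst_global": r.fst_global}
        for key in ("YRI_CHB", "YRI_CEU", "CEU_CHB"):
            row[f"fst_{key.lower()}"] = r.fst_pairwise.get(key, math.nan)
        for pop in POPULATIONS:
            row[f"h_{pop.lower()}"] = r.h.get(pop, math.nan)
        for pop in POPULATIONS:
            row[f"d_{pop.lower()}"] = r.tajima_d.get(pop, math.nan)
        for pop in POPULATIONS:
            row[f"ihs_{pop.lower()}"] = r.ihs.get(pop, math.nan)
        for pop in POPULATIONS:
            row[f"daf_{pop.lower()}"] = r.daf.get(pop, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
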