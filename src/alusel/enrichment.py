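"""SNP-density comparisons and the length-matched random-gene-set null.

Region classes compared (per gene): miRNA targets inside exonized Alus,
miRNA targets in non-Alu 3'UTR sequence (canonical sites), and exonized Alu
sequence without targets.  Group contrasts use the Mann–Whitney–Wilcoxon
test on per-gene densities; scaled-count contrasts use Welch's t.  The
permutation null draws random sets of 30-35 genes matched to the test set's
3'UTR length profile and flags the test set when its summed metric exceeds
the null mean + 3 SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DensityRecord",
    "NullDistribution",
    "snp_density",
    "mann_whitney_u",
    "two_sample_t",
    "random_geneset_null",
    "group_density_comparison",
]

REGION_CLASSES = (
    "alu_mirna_target",
    "utr_nonalu_mirna_target",
    "alu_no_target",
    "full_utr3",
)


@dataclass
class DensityRecord:
    gene: str
    region_class: str
    bp: int
    n_snps: int
    high_fst_snps: int = 0
    high_ihs_snps: int = 0

    @property
    def density(self) -> float:
        return self.n_snps / self.bp if self.bp > 0 else math.nan


def snp_density(
    regions: Sequence[tuple[int, int]], snp_positions: Sequence[int]
) -> tuple[int, int, float]:
    """(n_snps, total_bp, density) of SNPs falling in half-open regions.

    ``regions`` must be merged and non-overlapping; density is NaN for an
    empty region set.
    """
    bp = sum(e - s for s, e in regions)
    n = sum(1 for p in snp_positions if any(s <= p < e for s, e in regions))
    return n, bp, (n / bp if bp > 0 else math.nan)


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Mann–Whitney–Wilcoxon U (of x) and two-sided p.

    ``mode``: "exact" enumerates all label assignments (ties handled by
    midranks), "normal" uses the tie-corrected normal approximation with
    continuity correction, "auto" picks exact when n_x + n_y <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if np.all(np.concatenate([x, y]) == x[0]):
        return u, 1.0
    if mode == "auto":
        mode = "exact" if x.size + y.size <= 12 else "normal"
    if mode == "exact":
        pooled = np.concatenate([x, y])
        n, nx = pooled.size, x.size
        us = []
        for combo in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p = 2.0 * min((us <= u + eps).mean(), (us >= u - eps).mean())
        return u, min(1.0, p)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Welch's t (pooled-variance optional) and two-sided p.

    Zero variance in both samples gives p = 1 at equal means and a
    degenerate (t = +/-inf, p = 0) flag otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Random gene-set permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    metric: str
    n_iter: int
    set_size_range: tuple[int, int]
    values: np.ndarray
    test_value: float
    mean: float = field(init=False)
    sd: float = field(init=False)
    z: float = field(init=False)
    exceeds_3sd: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_iter:
            raise ValueError("values length must equal n_iter")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1))
        self.z = (
            (self.test_value - self.mean) / self.sd if self.sd > 0 else math.nan
        )
        self.exceeds_3sd = self.test_value > self.mean + 3 * self.sd


def _decile_bins(lengths: Mapping[str, float], n_bins: int = 10):
    genes = sorted(lengths)
    vals = np.array([lengths[g] for g in genes], dtype=float)
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.digitize(vals, edges[1:-1])
    bins: list[list[str]] = [[] for _ in range(n_bins)]
    for g, b in zip(genes, which):
        bins[int(b)].append(g)
    return edges, bins


def _profile_counts(profile: np.ndarray, m: int) -> np.ndarray:
    """Apportion m draws over bins proportional to profile (largest remainder)."""
    if profile.sum() == 0:
        raise ValueError("empty test-set length profile")
    quota = profile / profile.sum() * m
    base = np.floor(quota).astype(int)
    rem = m - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def random_geneset_null(
    gene_universe: Mapping[str, float],
    test_set: Mapping[str, float],
    metric: Mapping[str, float],
    n_iter: int = 1000,
    size_range: tuple[int, int] = (30, 35),
    seed: int = 0,
    metric_name: str = "metric",
    n_bins: int = 10,
) -> NullDistribution:
    """Length-matched random-gene-set null for a summed per-gene metric.

    ``gene_universe`` and ``test_set`` both map gene -> longest 3'UTR length
    (bp); the universe must exclude the test genes.  ``metric`` maps gene ->
    per-gene count (e.g. total SNPs, or SNPs with iHS > 2) and must cover
    both sets.  Each iteration draws a set of size uniform in ``size_range``
    whose composition across universe 3'UTR-length decile bins matches the
    test set's profile as closely as integer counts allow (largest-remainder
    apportionment, sampling without replacement within bins), then sums the
    metric.  Deterministic for a given seed.
    """
    overlap = set(test_set) & set(gene_universe)
    if overlap:
        raise ValueError(f"gene_universe must exclude the test set: {sorted(overlap)[:5]}")
    for g in list(test_set) + list(gene_universe):
        if g not in metric:
            raise KeyError(f"gene {g} has no metric value")
    rng = np.random.default_rng(seed)
    edges, bins = _decile_bins(gene_universe, n_bins)
    test_len = np.array([test_set[g] for g in sorted(test_set)], dtype=float)
    profile = np.array(
        [
            ((test_len >= edges[b]) & (test_len < edges[b + 1])).sum()
            for b in range(n_bins)
        ],
        dtype=float,
    )
    test_value = float(sum(metric[g] for g in test_set))
    lo, hi = size_range
    values = np.empty(n_iter)
    for it in range(n_iter):
        m = int(rng.integers(lo, hi + 1))
        counts = _profile_counts(profile, m)
        total = 0.0
        for b, k in enumerate(counts):
            if k == 0:
                continue
            if k > len(bins[b]):
                raise ValueError(
                    f"universe decile bin {b} has only {len(bins[b])} genes, "
                    f"need {k}"
                )
            chosen = rng.choice(len(bins[b]), size=k, replace=False)
            total += sum(metric[bins[b][i]] for i in chosen)
        values[it] = total
    return NullDistribution(
        metric=metric_name,
        n_iter=n_iter,
        set_size_range=(lo, hi),
        values=values,
        test_value=test_value,
    )


# ---------------------------------------------------------------------------
# Group density contrasts
# ---------------------------------------------------------------------------

def group_density_comparison(
    records: Sequence[DensityRecord],
    metrics: Sequence[str] = ("density", "high_fst_density"),
    mode: str = "auto",
):
    """Pairwise Mann–Whitney contrasts of per-gene densities between classes.

    Returns a DataFrame with one row per (class pair, metric): the U
    statistic of the first class, the two-sided p, and the direction of the
    median difference.  Requires >= 2 genes per compared class.
    """
    import pandas as pd

    def metric_value(rec: DensityRecord, name: str) -> float:
        if name == "density":
            return rec.density
        if name == "high_fst_density":
            return rec.high_fst_snps / rec.bp if rec.bp else math.nan
        if name == "high_ihs_density":
            return rec.high_ihs_snps / rec.bp if rec.bp else math.nan
        raise KeyError(name)

    by_class: dict[str, list[DensityRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.region_class, []).append(rec)
    rows = []
    classes = [c for c in REGION_CLASSES if c in by_class]
    for ca, cb in combinations(classes, 2):
        for name in metrics:
            xa = [metric_value(r, name) for r in by_class[ca]]
            xb = [metric_value(r, name) for r in by_class[cb]]
            xa = [v for v in xa if not math.isnan(v)]
            xb = [v for v in xb if not math.isnan(v)]
            if len(xa) < 2 or len(xb) < 2:
                continue
            u, p = mann_whitney_u(xa, xb, mode=mode)
            da, db = float(np.median(xa)), float(np.median(xb))
            direction = f"{ca}>{cb}" if da > db else (
                f"{ca}<{cb}" if da < db else "~"
            )
            rows.append(
                {"class_a": ca, "class_b": cb, "metric": name,
                 "U": u, "p": p, "direction": direction}
            )
    return pd.DataFrame(rows)
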