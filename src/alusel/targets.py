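"""miRNA target-site prediction in 3'UTR sequences.

Two predictors are provided:

* :func:`find_seed_sites` — canonical seed-type matching (8mer, 7mer-m8,
  7mer-A1, 6mer), with overlapping hits reported at the strongest type only.
* :func:`align_miranda_like` — Smith–Waterman-style local alignment of the
  reversed miRNA against the target with Watson–Crick/wobble pair scores,
  affine gaps, and seed-region score scaling.

A consensus rule combines the two: a (UTR, miRNA) pair predicted by both
tools is kept only when the predicted positions agree (overlap); when both
tools call the miRNA on the UTR but at discordant positions the pair is
excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MiRNA",
    "AlignmentParams",
    "TargetSite",
    "read_mirna_fasta",
    "find_seed_sites",
    "align_miranda_like",
    "duplex_energy",
    "consensus_targets",
    "classify_alu_sites",
    "revcomp_rna",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_TYPE_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "alignment": 0}


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU(T) characters in sequence: {sorted(bad)}")
    return s


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(_to_rna(seq)))


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', RNA alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _to_rna(self.sequence))
        if len(self.sequence) < 18:
            raise ValueError(f"{self.name}: mature miRNA shorter than 18 nt")

    @property
    def seed6(self) -> str:
        """Positions 2-7 (1-based)."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Positions 2-8 (1-based)."""
        return self.sequence[1:8]


def read_mirna_fasta(path: str) -> list[MiRNA]:
    """Read mature miRNA sequences from FASTA (first token of header = name)."""
    out: list[MiRNA] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out.append(MiRNA(name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        out.append(MiRNA(name, "".join(chunks)))
    return out


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the alignment predictor.

    Defaults follow the common miRanda-style configuration: gap open -8.0,
    gap extend -2.0, Watson-Crick pair +5, G:U wobble +1, mismatch -3, and a
    4x scale on score contributions from miRNA seed positions 2-8.  The score
    threshold is 50 in expression-analysis mode and 100 (with strict seed) in
    genome-wide mode.
    """

    gap_open: float = -8.0
    gap_extend: float = -2.0
    score_threshold: float = 50.0
    energy_threshold: float | None = None
    scale: float = 4.0
    strict_seed: bool = False
    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    seed_span: tuple[int, int] = (2, 8)  # 1-based miRNA positions, inclusive

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    @classmethod
    def expression_mode(cls) -> "AlignmentParams":
        return cls(score_threshold=50.0, energy_threshold=-20.0, strict_seed=False)

    @classmethod
    def genomewide_mode(cls) -> "AlignmentParams":
        return cls(score_threshold=100.0, energy_threshold=None, strict_seed=True)


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA site, 0-based half-open in UTR coordinates."""

    utr_id: str
    mirna_name: str
    start: int
    end: int
    site_type: str
    predictor: str
    score: float = 0.0
    in_alu: bool = False
    alu_exclusive: bool = False
    pairs: tuple[tuple[str, str], ...] = ()  # aligned (target, mirna) base pairs

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid site span")

    def overlap_bp(self, other: "TargetSite") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# Seed-type predictor
# ---------------------------------------------------------------------------

def find_seed_sites(utr_seq: str, mirna: MiRNA, utr_id: str = "utr") -> list[TargetSite]:
    """All canonical seed matches of ``mirna`` in ``utr_seq``.

    Site types, strongest first: 8mer (complement of positions 2-8 followed
    by A), 7mer-m8 (complement of 2-8), 7mer-A1 (complement of 2-7 followed
    by A), 6mer (complement of 2-7).  Overlapping hits are reported once, at
    the strongest applicable type.
    """
    seq = _to_rna(utr_seq)
    core = revcomp_rna(mirna.seed6)      # 6 nt, complement of positions 2-7
    m8_pair = _RNA_COMPLEMENT[mirna.sequence[7]]  # target base pairing position 8
    sites: list[TargetSite] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == m8_pair
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            stype, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            stype, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            stype, start, end = "7mer-A1", i, i + 7
        else:
            stype, start, end = "6mer", i, i + 6
        sites.append(
            TargetSite(utr_id, mirna.name, start, end, stype, predictor="seed_like")
        )
        i = seq.find(core, i + 1)
    return sites


# ---------------------------------------------------------------------------
# Alignment predictor
# ---------------------------------------------------------------------------

def _pair_score(t: str, m: str, params: AlignmentParams) -> float:
    if _RNA_COMPLEMENT[m] == t:
        return params.match_wc
    if (t, m) in (("G", "U"), ("U", "G")):
        return params.match_gu
    return params.mismatch


def _is_wc(t: str, m: str) -> bool:
    return _RNA_COMPLEMENT[m] == t


def _align_region(
    seq: str, mirna: MiRNA, params: AlignmentParams, offset: int
) -> tuple[float, int, int, list[tuple[int | None, int | None]]] | None:
    """Best local (Gotoh affine-gap) alignment of reversed miRNA vs ``seq``.

    Returns (score, target_start, target_end, path) where path entries are
    (target_index, mirna_position_1based), either side None for a gap.
    """
    n, y = len(seq), mirna.sequence[::-1]
    m = len(y)
    if n < 6:
        return None
    lo, hi = params.seed_span
    NEG = -1e18
    go, ge = params.gap_open, params.gap_extend
    # M: ends with an aligned pair; Ix: gap in miRNA (target base consumed);
    # Iy: gap in target (miRNA base consumed).
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[0] * (m + 1) for _ in range(n + 1)]   # 0 start, 1 M, 2 Ix, 3 Iy
    pIx = [[1] * (m + 1) for _ in range(n + 1)]  # 1 open from M, 2 extend
    pIy = [[1] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ti = seq[i - 1]
        Mi, Mp, Ixi, Ixp, Iyi = M[i], M[i - 1], Ix[i], Ix[i - 1], Iy[i]
        Iyp = Iy[i - 1]
        for j in range(1, m + 1):
            pos = m - (j - 1)  # 1-based miRNA position of y[j-1]
            s = _pair_score(ti, y[j - 1], params)
            if lo <= pos <= hi:
                s *= params.scale
            d1, d2, d3 = Mp[j - 1], Ixp[j - 1], Iyp[j - 1]
            if d1 >= d2 and d1 >= d3:
                dbest, src = d1, 1
            elif d2 >= d3:
                dbest, src = d2, 2
            else:
                dbest, src = d3, 3
            if dbest <= 0.0:
                dbest, src = 0.0, 0  # fresh local start
            val = dbest + s
            if val <= 0.0:
                Mi[j] = 0.0
                pM[i][j] = 0
            else:
                Mi[j] = val
                pM[i][j] = src
                if val > best:
                    best, bi, bj = val, i, j
            o, e = Mp[j] + go, Ixp[j] + ge
            if o >= e:
                Ixi[j], pIx[i][j] = o, 1
            else:
                Ixi[j], pIx[i][j] = e, 2
            o, e = Mi[j - 1] + go, Iyi[j - 1] + ge
            if o >= e:
                Iyi[j], pIy[i][j] = o, 1
            else:
                Iyi[j], pIy[i][j] = e, 2
    if best < params.score_threshold:
        return None
    path: list[tuple[int | None, int | None]] = []
    i, j, state = bi, bj, "M"
    while i > 0 and j > 0:
        if state == "M":
            path.append((i - 1, m - (j - 1)))
            src = pM[i][j]
            i, j = i - 1, j - 1
            if src == 0:
                break
            state = {1: "M", 2: "Ix", 3: "Iy"}[src]
        elif state == "Ix":
            path.append((i - 1, None))
            state = "M" if pIx[i][j] == 1 else "Ix"
            i -= 1
        else:
            path.append((None, m - (j - 1)))
            state = "M" if pIy[i][j] == 1 else "Iy"
            j -= 1
    path.reverse()
    t_idx = [p[0] for p in path if p[0] is not None]
    return best, min(t_idx) + offset, max(t_idx) + 1 + offset, [
        (p[0] + offset if p[0] is not None else None, p[1]) for p in path
    ]


def _strict_seed_ok(seq_full: str, mirna: MiRNA, path) -> bool:
    """Positions 2-7 must all be aligned, gap-free, Watson-Crick."""
    aligned = {p[1]: p[0] for p in path}
    prev_t = None
    for pos in range(7, 1, -1):  # target indices increase as pos decreases
        t = aligned.get(pos)
        if t is None:
            return False
        if not _is_wc(seq_full[t], mirna.sequence[pos - 1]):
            return False
        if prev_t is not None and t != prev_t + 1:
            return False
        prev_t = t
    return True


def align_miranda_like(
    utr_seq: str,
    mirna: MiRNA,
    params: AlignmentParams | None = None,
    utr_id: str = "utr",
) -> list[TargetSite]:
    """Alignment-scored sites of ``mirna`` in ``utr_seq``.

    Non-overlapping sites are reported greedily by score: the best-scoring
    local alignment above threshold is taken, its target span is excluded,
    and the flanking segments are searched recursively.  With
    ``params.strict_seed`` an alignment whose seed (miRNA positions 2-7) is
    not a contiguous gap-free Watson-Crick duplex is rejected.  With
    ``params.energy_threshold`` set, sites whose duplex energy exceeds the
    threshold are dropped.
    """
    params = params or AlignmentParams()
    seq = _to_rna(utr_seq)
    sites: list[TargetSite] = []
    stack = [(0, len(seq))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 6:
            continue
        hit = _align_region(seq[lo:hi], mirna, params, lo)
        if hit is None:
            continue
        score, start, end, path = hit
        stack.append((lo, start))
        stack.append((end, hi))
        if params.strict_seed and not _strict_seed_ok(seq, mirna, path):
            continue
        pairs = tuple(
            (seq[t], mirna.sequence[p - 1])
            for t, p in path
            if t is not None and p is not None
        )
        if params.energy_threshold is not None:
            if duplex_energy(pairs) > params.energy_threshold:
                continue
        sites.append(
            TargetSite(
                utr_id, mirna.name, start, end, "alignment",
                predictor="miranda_like", score=score, pairs=pairs,
            )
        )
    sites.sort(key=lambda s: (-s.score, s.start))
    return sites


def duplex_energy(pairs: Iterable[tuple[str, str]]) -> float:
    """Additive duplex stability in kcal/mol.

    G:C pairs contribute -3.0, A:U -2.0, G:U -1.0, with a +4.0 duplex
    initiation penalty.  Mismatched aligned bases contribute nothing.  This
    deliberately simple stacking-free model stands in for a nearest-neighbor
    thermodynamic calculation; it is monotone in pairing strength, which is
    all the energy-threshold filter requires.
    """
    e = 4.0
    for t, m in pairs:
        pair = frozenset((t, m))
        if pair == frozenset(("G", "C")):
            e -= 3.0
        elif pair == frozenset(("A", "U")):
            e -= 2.0
        elif pair == frozenset(("G", "U")):
            e -= 1.0
    return e


# ---------------------------------------------------------------------------
# Consensus and Alu classification
# ---------------------------------------------------------------------------

def consensus_targets(
    sites_a: Sequence[TargetSite],
    sites_b: Sequence[TargetSite],
    min_overlap: int = 1,
) -> list[TargetSite]:
    """Position-concordant consensus of two predictors.

    For each (UTR, miRNA) pair present in both inputs, keep the sites from
    ``sites_a`` that overlap a ``sites_b`` site by >= ``min_overlap`` bp
    (relabelled predictor="consensus").  A pair predicted by both tools but
    with no overlapping site positions is excluded entirely; a pair seen by
    only one tool is not emitted.
    """
    by_key_a: dict[tuple[str, str], list[TargetSite]] = {}
    by_key_b: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites_a:
        by_key_a.setdefault((s.utr_id, s.mirna_name), []).append(s)
    for s in sites_b:
        by_key_b.setdefault((s.utr_id, s.mirna_name), []).append(s)
    out: list[TargetSite] = []
    for key in sorted(set(by_key_a) & set(by_key_b)):
        for sa in by_key_a[key]:
            if any(sa.overlap_bp(sb) >= min_overlap for sb in by_key_b[key]):
                out.append(replace(sa, predictor="consensus"))
    return out


def classify_alu_sites(
    sites: Sequence[TargetSite],
    alu_segments: Mapping[str, Sequence[tuple[int, int]]],
    gene_of: Mapping[str, str] | None = None,
    min_fraction: float = 0.5,
) -> list[TargetSite]:
    """Set ``in_alu`` and ``alu_exclusive`` on predicted sites.

    ``alu_segments`` maps utr_id -> half-open Alu spans in the same (UTR)
    coordinate system as the sites.  A site is in_alu when its overlap with
    any Alu span covers >= ``min_fraction`` of the site length.  A (gene,
    miRNA) pair is alu_exclusive when every one of its sites is in_alu.
    """
    gene_of = gene_of or {}
    flagged: list[TargetSite] = []
    for s in sites:
        ov = 0
        for a0, a1 in alu_segments.get(s.utr_id, ()):
            ov = max(ov, min(s.end, a1) - max(s.start, a0))
        flagged.append(replace(s, in_alu=ov >= min_fraction * (s.end - s.start)))
    all_alu: dict[tuple[str, str], bool] = {}
    for s in flagged:
        key = (gene_of.get(s.utr_id, s.utr_id), s.mirna_name)
        all_alu[key] = all_alu.get(key, True) and s.in_alu
    return [
        replace(s, alu_exclusive=all_alu[(gene_of.get(s.utr_id, s.utr_id), s.mirna_name)])
        for s in flagged
    ]


def write_sites_tsv(sites: Sequence[TargetSite], path: str) -> None:
    cols = "utr_id\tmirna\tstart\tend\ttype\tscore\tpredictor\tin_alu\talu_exclusive\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for s in sorted(sites, key=lambda s: (s.utr_id, s.mirna_name, s.start)):
            fh.write(
                f"{s.utr_id}\t{s.mirna_name}\t{s.start}\t{s.end}\t{s.site_type}\t"
                f"{s.score:g}\t{s.predictor}\t{int(s.in_alu)}\t{int(s.alu_exclusive)}\n"
            )
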