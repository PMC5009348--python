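"""Synthetic inputs with controlled ground truth.

Two generators:

* :func:`simulate_annotation` — gene 3'UTRs carrying mutated copies of a
  packaged synthetic Alu-like consensus, with exact miRNA seed-complement
  sites planted inside or outside the Alu copies and a truth table of every
  planted site.
* :func:`simulate_balding_nichols` / :func:`simulate_wright_fisher` — three-
  population haplotype panels.  The Balding–Nichols model gives independent
  SNPs with known expected F_ST (validates the frequency-based statistics);
  the forward Wright–Fisher model gives linked haplotypes after a three-way
  population split, with an optional additive sweep in one population
  (validates H, D and iHS).  The ancestral population at the split is drawn
  at mutation–drift equilibrium with msprime; the post-split generations are
  simulated forward with random mating, Poisson crossovers and infinite-
  sites mutation.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .popgen import HaplotypePanel
from .targets import MiRNA, revcomp_rna

__all__ = [
    "GenomeSimConfig",
    "PopSimConfig",
    "SimulatedAnnotation",
    "simulate_annotation",
    "simulate_balding_nichols",
    "simulate_wright_fisher",
    "write_vcf",
    "write_panel_tsv",
    "load_alu_consensus",
]

_DNA = np.array(list("ACGT"))
_ALU_SUBFAMILIES = ("AluY", "AluSx", "AluJo")


def load_alu_consensus() -> str:
    """The packaged ~300-nt synthetic Alu-like consensus (DNA alphabet)."""
    src = resources.files("alusel").joinpath("data", "alu_consensus_synthetic.fa")
    lines = src.read_text().splitlines()
    return "".join(l.strip() for l in lines if not l.startswith(">"))


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    n_genes: int = 50
    utr3_log_mean: float = math.log(1200.0)   # log-normal UTR length, median 1.2 kb
    utr3_log_sigma: float = 0.45
    alu_insertion_rate: float = 1.0           # expected Alu copies per UTR
    alu_divergence: float = 0.10              # per-base substitution vs consensus
    planted_mirnas: Sequence[MiRNA] = ()
    plant_prob_in_alu: float = 1.0
    plant_prob_outside: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in (self.plant_prob_in_alu, self.plant_prob_outside):
            if not 0.0 <= p <= 1.0:
                raise ValueError("plant probabilities must be in [0, 1]")


@dataclass
class SimulatedAnnotation:
    """In-memory bundle of the generated annotation."""

    utr_seqs: dict[str, str]                       # gene -> UTR DNA sequence
    gene_intervals: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    repeats: list[tuple[str, int, int, str]]       # (chrom, start, end, subfamily)
    truth: list[dict]                              # planted sites

    def write(self, outdir: str) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "utr_fasta": os.path.join(outdir, "utr3.fa"),
            "gene_bed": os.path.join(outdir, "genes.bed"),
            "repeat_bed": os.path.join(outdir, "repeats.bed"),
            "truth_tsv": os.path.join(outdir, "planted_sites.tsv"),
        }
        with open(paths["utr_fasta"], "w") as fh:
            for gene in sorted(self.utr_seqs):
                fh.write(f">{gene}\n")
                seq = self.utr_seqs[gene]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["gene_bed"], "w") as fh:
            for gene in sorted(self.gene_intervals):
                chrom, s, e = self.gene_intervals[gene]
                fh.write(f"{chrom}\t{s}\t{e}\t{gene}\t0\t+\n")
        with open(paths["repeat_bed"], "w") as fh:
            for chrom, s, e, name in self.repeats:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t+\n")
        with open(paths["truth_tsv"], "w") as fh:
            fh.write("gene\tmirna\tstart\tend\tin_alu\n")
            for t in self.truth:
                fh.write(
                    f"{t['gene']}\t{t['mirna']}\t{t['start']}\t{t['end']}\t"
                    f"{int(t['in_alu'])}\n"
                )
        return paths

    def alu_segments(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {g: [] for g in self.utr_seqs}
        for chrom, s, e, _ in self.repeats:
            out[chrom].append((s, e))
        return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _site_8mer_dna(mirna: MiRNA) -> str:
    """Exact 8mer site (DNA): complement of positions 2-8 followed by A."""
    return (revcomp_rna(mirna.seed7) + "A").replace("U", "T")


def simulate_annotation(config: GenomeSimConfig) -> SimulatedAnnotation:
    """Generate UTR sequences, Alu annotations and planted miRNA sites.

    Each gene occupies its own contig (named after the gene) starting at 0 on
    the + strand, so UTR-relative and genomic coordinates coincide; the
    interval machinery is exercised through the emitted BED files.  Alu
    copies overwrite (rather than lengthen) the background sequence at
    non-overlapping positions.  Planted sites are written after Alu
    insertion, so they survive verbatim and the truth table is exact.
    """
    rng = np.random.default_rng(config.seed)
    consensus = load_alu_consensus()
    utr_seqs: dict[str, str] = {}
    gene_intervals: dict[str, tuple[str, int, int]] = {}
    repeats: list[tuple[str, int, int, str]] = []
    truth: list[dict] = []
    subfam_i = 0
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        length = max(
            400, int(rng.lognormal(config.utr3_log_mean, config.utr3_log_sigma))
        )
        seq = list(rng.choice(_DNA, size=length))
        # Alu insertions: non-overlapping replacement copies of the consensus
        n_alu = rng.poisson(config.alu_insertion_rate)
        alu_spans: list[tuple[int, int]] = []
        for _ in range(n_alu):
            if length < len(consensus) + 2:
                break
            for _attempt in range(20):
                start = int(rng.integers(0, length - len(consensus)))
                span = (start, start + len(consensus))
                if all(span[1] <= s or span[0] >= e for s, e in alu_spans):
                    alu_spans.append(span)
                    copy = _mutate(consensus, config.alu_divergence, rng)
                    seq[span[0] : span[1]] = list(copy)
                    repeats.append(
                        (gene, span[0], span[1], _ALU_SUBFAMILIES[subfam_i % 3])
                    )
                    subfam_i += 1
                    break
        # plant miRNA sites
        for mir in config.planted_mirnas:
            site = _site_8mer_dna(mir)
            if len(site) >= length:
                raise ValueError("planted site longer than host region")
            if alu_spans and rng.random() < config.plant_prob_in_alu:
                s0, e0 = alu_spans[int(rng.integers(len(alu_spans)))]
                start = int(rng.integers(s0, e0 - len(site) + 1))
                seq[start : start + len(site)] = list(site)
                truth.append(
                    {"gene": gene, "mirna": mir.name, "start": start,
                     "end": start + len(site), "in_alu": True}
                )
            if rng.random() < config.plant_prob_outside:
                # choose a start outside every Alu span
                for _attempt in range(50):
                    start = int(rng.integers(0, length - len(site)))
                    if all(
                        start + len(site) <= s or start >= e for s, e in alu_spans
                    ):
                        seq[start : start + len(site)] = list(site)
                        truth.append(
                            {"gene": gene, "mirna": mir.name, "start": start,
                             "end": start + len(site), "in_alu": False}
                        )
                        break
        utr_seqs[gene] = "".join(seq)
        gene_intervals[gene] = (gene, 0, length)
    return SimulatedAnnotation(utr_seqs, gene_intervals, repeats, truth)


# ---------------------------------------------------------------------------
# Population generators
# ---------------------------------------------------------------------------

POP_LABELS = ("CEU", "CHB", "YRI")


@dataclass
class PopSimConfig:
    model: str = "balding_nichols"
    diploids_per_pop: int = 100
    n_snps: int = 500                     # balding_nichols only
    F: float = 0.1                        # balding_nichols differentiation
    chromosome_length: int = 200_000      # wright_fisher only
    mu: float = 5e-7                      # per bp per gamete (rescaled small-N units)
    recomb_rate: float = 1e-7             # per bp per gamete
    ancestral_Ne: int | None = None       # msprime equilibrium size; default = pop size
    generations: int = 200                # post-split forward generations
    selection: tuple[str, float, int] | None = None  # (pop, s, onset_gen)
    sweep_target_freq: float = 0.8        # sample at first crossing (incomplete sweep)
    max_attempts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.F < 0.8:
            raise ValueError("F must be in [0, 0.8)")
        if self.selection is not None and self.selection[1] < 0:
            raise ValueError("selection coefficient must be >= 0")


def sweep_study_config(
    seed: int, selection: tuple[str, float, int] | None = None
) -> PopSimConfig:
    """The fixed study conditions for sweep-versus-neutral contrasts.

    Three populations of 200 diploids (2N = 400 haplotypes each) at constant
    size, a 200 kb region with rescaled per-gamete rates mu = 5e-7/bp and
    r = 1e-7/bp, 200 post-split generations; a sweep, when requested, is
    additive with the given coefficient from the given onset generation and
    is sampled at the first crossing of derived frequency 0.88 (an
    incomplete sweep, where the Fay–Wu's H and iHS footprints are
    strongest).
    """
    return PopSimConfig(
        model="wright_fisher_forward",
        diploids_per_pop=200,
        chromosome_length=200_000,
        mu=5e-7,
        recomb_rate=1e-7,
        ancestral_Ne=200,
        generations=200,
        selection=selection,
        sweep_target_freq=0.88,
        seed=seed,
    )


def simulate_balding_nichols(config: PopSimConfig) -> HaplotypePanel:
    """Independent SNPs with Beta-distributed per-population frequencies.

    Per SNP: ancestral frequency p0 ~ U(0.05, 0.95); each population's
    frequency ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) (exactly p0 when F = 0);
    haplotypes drawn independently (no linkage).  Alleles are coded
    1 = derived with full polarity.
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.diploids_per_pop
    S = config.n_snps
    p0 = rng.uniform(0.05, 0.95, size=S)
    cols = []
    for _pop in POP_LABELS:
        if config.F == 0.0:
            p = p0
        else:
            c = (1.0 - config.F) / config.F
            p = rng.beta(p0 * c, (1.0 - p0) * c)
        cols.append((rng.random((n_hap, S)) < p).astype(np.int8))
    alleles = np.vstack(cols)
    positions = np.arange(1, S + 1) * 1000  # evenly spaced; no LD anyway
    pops = np.repeat(POP_LABELS, n_hap)
    return HaplotypePanel(
        positions=positions,
        alleles=alleles,
        pops=pops,
        polarized=np.ones(S, dtype=bool),
        snp_ids=[f"snp{i:05d}" for i in range(S)],
    )


def _msprime_ancestral(
    n_hap_total: int, L: int, mu: float, r: float, N_anc: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium ancestral panel (haplotypes x sites, positions)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_hap_total // 2,
        population_size=N_anc,
        sequence_length=L,
        recombination_rate=r,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=max(1, (seed + 1) % (2**31 - 1)),
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    gm = ts.genotype_matrix()  # sites x haplotypes
    positions = np.array([s.position for s in ts.sites()])
    keep = np.ones(len(positions), dtype=bool)
    return gm.T.astype(np.int8)[:, keep], positions[keep]


class _ForwardSim:
    """Forward Wright–Fisher on a shared site registry across populations."""

    def __init__(self, alleles: np.ndarray, positions: np.ndarray,
                 pop_slices: list[slice], L: int, mu: float, r: float,
                 rng: np.random.Generator):
        self.H = alleles            # (total_haps, S) int8
        self.pos = positions        # float positions
        self.pop_slices = pop_slices
        self.L = L
        self.mu_total = mu * L
        self.r_total = r * L
        self.rng = rng

    def _gametes(self, block: np.ndarray, n_out: int,
                 fitness: np.ndarray | None) -> np.ndarray:
        """n_out gametes from a diploid block (2k haplotypes)."""
        k = block.shape[0] // 2
        if fitness is None:
            parents = self.rng.integers(0, k, size=n_out)
        else:
            p = fitness / fitness.sum()
            parents = self.rng.choice(k, size=n_out, p=p)
        a = block[2 * parents]
        b = block[2 * parents + 1]
        pick = self.rng.integers(0, 2, size=n_out)
        out = np.where(pick[:, None] == 0, a, b)
        n_co = self.rng.poisson(self.r_total, size=n_out)
        for i in np.flatnonzero(n_co):
            cuts = np.sort(self.rng.uniform(0, self.L, size=n_co[i]))
            phase = pick[i] + np.searchsorted(cuts, self.pos)
            out[i] = np.where(phase % 2 == 0, a[i], b[i])
        return out.astype(np.int8)

    def step(self, sel_pop: int | None = None, s: float = 0.0,
             sel_pos: float | None = None) -> None:
        new_blocks = []
        sel_col = None
        if sel_pos is not None:
            hits = np.flatnonzero(self.pos == sel_pos)
            sel_col = int(hits[0]) if hits.size else None
        for k, sl in enumerate(self.pop_slices):
            block = self.H[sl]
            fitness = None
            if sel_pop == k and sel_col is not None and s > 0:
                g = block[0::2, sel_col].astype(float) + block[1::2, sel_col]
                fitness = 1.0 + s * g
            new_blocks.append(self._gametes(block, block.shape[0], fitness))
        self.H = np.vstack(new_blocks)
        # infinite-sites mutations: one new column per event
        n_mut = self.rng.poisson(self.mu_total * self.H.shape[0])
        if n_mut:
            newcols = np.zeros((self.H.shape[0], n_mut), dtype=np.int8)
            carriers = self.rng.integers(0, self.H.shape[0], size=n_mut)
            newcols[carriers, np.arange(n_mut)] = 1
            self.H = np.hstack([self.H, newcols])
            self.pos = np.concatenate(
                [self.pos, self.rng.uniform(0, self.L, size=n_mut)]
            )

    def prune(self, keep_pos: float | None = None) -> None:
        tot = self.H.sum(axis=0)
        keep = (tot > 0) & (tot < self.H.shape[0])
        if keep_pos is not None:
            keep |= self.pos == keep_pos
        self.H = self.H[:, keep]
        self.pos = self.pos[keep]

    def freq(self, position: float, sl: slice) -> float:
        hits = np.flatnonzero(self.pos == position)
        if hits.size == 0:
            return 0.0
        return float(self.H[sl, hits[0]].mean())


def simulate_wright_fisher(config: PopSimConfig) -> HaplotypePanel:
    """Forward Wright–Fisher panel: 3-way split, drift, recombination,
    infinite-sites mutation and an optional additive sweep.

    The shared ancestral population at the split is drawn at mutation–drift
    equilibrium with msprime (``ancestral_Ne`` defaults to the per-population
    size, i.e. constant population size through the split; a larger value
    models a contraction at the split).  Each population then evolves
    independently for ``config.generations``.  With ``config.selection = (pop, s, onset)`` a
    new beneficial mutation (additive fitness 1, 1+s, 1+2s) is introduced at
    the region midpoint in one haplotype of that population at generation
    ``onset``; the run is sampled at the first generation where the allele
    frequency reaches ``sweep_target_freq`` (an incomplete sweep, where the
    Fay–Wu's H and iHS footprints are strongest).  Runs in which the allele
    is lost, or never reaches the target within ``generations``, are
    re-simulated from the onset checkpoint with an incremented sub-seed, up
    to ``max_attempts``.
    """
    N = config.diploids_per_pop
    n_hap = 2 * N
    L = config.chromosome_length
    N_anc = config.ancestral_Ne if config.ancestral_Ne is not None else N
    anc, pos = _msprime_ancestral(
        3 * n_hap, L, config.mu, config.recomb_rate, N_anc, config.seed
    )
    rng = np.random.default_rng(config.seed)
    slices = [slice(k * n_hap, (k + 1) * n_hap) for k in range(3)]
    sim = _ForwardSim(anc, pos, slices, L, config.mu, config.recomb_rate, rng)

    sel_pop_idx: int | None = None
    s = 0.0
    onset = config.generations + 1
    sel_pos = float(L) / 2.0
    if config.selection is not None:
        pop_label, s, onset = config.selection
        sel_pop_idx = POP_LABELS.index(pop_label)

    for gen in range(min(onset, config.generations)):
        sim.step()
        if gen % 25 == 24:
            sim.prune()

    if sel_pop_idx is not None and onset < config.generations:
        sim.prune()
        ckpt_H, ckpt_pos = sim.H.copy(), sim.pos.copy()
        for attempt in range(config.max_attempts):
            sub = np.random.default_rng(
                (config.seed * 1000 + attempt + 1) % (2**31 - 1)
            )
            sim.H, sim.pos, sim.rng = ckpt_H.copy(), ckpt_pos.copy(), sub
            # introduce the beneficial allele in one haplotype of the pop
            col = np.zeros((sim.H.shape[0], 1), dtype=np.int8)
            carrier = slices[sel_pop_idx].start + int(sub.integers(0, n_hap))
            col[carrier, 0] = 1
            sim.H = np.hstack([sim.H, col])
            sim.pos = np.concatenate([sim.pos, [sel_pos]])
            reached = False
            for gen in range(onset, config.generations):
                sim.step(sel_pop=sel_pop_idx, s=s, sel_pos=sel_pos)
                if gen % 25 == 24:
                    sim.prune(keep_pos=sel_pos)
                f = sim.freq(sel_pos, slices[sel_pop_idx])
                if f == 0.0:
                    break
                if f >= config.sweep_target_freq:
                    reached = True
                    break
            if reached:
                break
        else:
            raise RuntimeError(
                f"selected allele never reached frequency "
                f"{config.sweep_target_freq} in {config.max_attempts} attempts"
            )
    sim.prune(keep_pos=sel_pos if sel_pop_idx is not None else None)

    order = np.argsort(sim.pos)
    pos_sorted = sim.pos[order]
    # integerize positions, enforcing strict increase
    pos_int = np.floor(pos_sorted).astype(int)
    for i in range(1, len(pos_int)):
        if pos_int[i] <= pos_int[i - 1]:
            pos_int[i] = pos_int[i - 1] + 1
    ids = [f"pos{int(p)}" for p in pos_int]
    return HaplotypePanel(
        positions=pos_int,
        alleles=sim.H[:, order],
        pops=np.repeat(POP_LABELS, n_hap),
        polarized=np.ones(len(pos_int), dtype=bool),
        snp_ids=ids,
        chrom="sim1",
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write the panel as phased VCF 4.2 with the AA ancestral-allele tag."""
    n_samples = len(panel.pops) // 2
    samples = []
    for i in range(n_samples):
        pop = panel.pops[2 * i]
        samples.append(f"{pop}_{i:04d}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for s in range(panel.n_sites):
            ref, alt = "A", "G"   # ancestral = REF by construction
            aa = ref if panel.polarized[s] else "."
            snp_id = panel.snp_ids[s] if panel.snp_ids else "."
            gts = []
            col = panel.alleles[:, s]
            for i in range(n_samples):
                a, b = col[2 * i], col[2 * i + 1]
                gts.append(
                    f"{'.' if a < 0 else a}|{'.' if b < 0 else b}"
                )
            fh.write(
                f"{panel.chrom}\t{int(panel.positions[s]) + 1}\t{snp_id}\t{ref}\t"
                f"{alt}\t.\tPASS\tAA={aa}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_panel_tsv(panel: HaplotypePanel, path: str) -> None:
    n_samples = len(panel.pops) // 2
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for i in range(n_samples):
            pop = panel.pops[2 * i]
            fh.write(f"{pop}_{i:04d}\t{pop}\n")
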