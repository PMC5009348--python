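# Methods

This note documents the models, the tunable parameters and their defaults,
the synthetic-data generators, and the design decisions that were genuinely
open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and annotation

All internal coordinates are 0-based half-open. BED is read natively;
RepeatMasker `.out` (1-based inclusive) and VCF (1-based) are converted on
read. Multi-transcript genes are analyzed on the union of their transcript
3′UTR intervals; the longest single annotated UTR length is stored
separately because per-gene SNP densities use it as the denominator. Alu
membership is by subfamily-name prefix (`Alu*`); FLAM/FRAM monomer fragments
count only when a flag is set (default off). UTR sequences are handled
5′→3′ on the transcript sense strand. A contig-name blacklist is exposed at
BED-filter level for assemblies with `*_random`/`*_hap`-style contigs.

## Target prediction

Two predictors, deliberately independent:

* **Seed scanner.** Canonical site types against the miRNA seed
  (positions 2–7/2–8): 8mer (complement of 2–8 + A), 7mer-m8, 7mer-A1,
  6mer. Overlapping hits are reported once at the strongest type. T/U are
  equivalent on input.
* **Alignment predictor.** Local (Gotoh affine-gap) alignment of the
  reversed miRNA against the target. Pair scores: Watson–Crick +5, G:U
  wobble +1, mismatch −3; gap open −8, extend −2; score contributions from
  miRNA positions 2–8 are multiplied by a scale (default 4). These pairing
  scores follow the widely used miRanda-style scheme and are configurable;
  only the gap penalties, thresholds and scale are externally fixed.
  Expression-analysis mode: score ≥ 50, duplex-energy filter at
  −20 kcal/mol. Genome-wide mode: score ≥ 100, strict seed (positions 2–7
  must be contiguous gap-free Watson–Crick pairs), no energy filter.
  Non-overlapping sites are reported greedily by score; when a best local
  alignment fails the strict-seed check its span is not re-searched — a
  deliberate simplification that keeps output deterministic.

The **duplex energy** is a simple additive model (G:C −3.0, A:U −2.0,
G:U −1.0 kcal/mol, +4.0 initiation). It is monotone in pairing strength,
which is all the threshold filter requires; it is not a nearest-neighbor
thermodynamic calculation and will not reproduce duplex folding energies.

The **consensus rule**: for each (UTR, miRNA) pair called by both
predictors, sites are kept (predictor = `consensus`) only when some site
pair overlaps by ≥ 1 bp (configurable); a pair called by both tools at
discordant positions is excluded entirely, and a pair called by one tool is
not emitted. A site is `in_alu` when ≥ 50% of its length lies in an Alu
segment; a (gene, miRNA) pair is `alu_exclusive` when all of its sites are.

## Selection statistics

Input is a phased haplotype panel, alleles coded 0 = ancestral / 1 = derived
via the VCF `AA` tag; sites where `AA` matches neither allele stay
unpolarized (REF = 0) and are used for F_ST only. Sites with > 10% missing
haplotypes in a population are dropped from that population's windows
(configurable).

* **F_ST.** Haploid (allele-level) Weir–Cockerham variance components; per
  SNP θ = a/(a+b), undefined (never 0) at monomorphic sites. The diploid
  1984 estimator with the heterozygosity term is available for unphased
  data. For recovering a simulation's differentiation parameter the
  multi-locus form Σa/Σ(a+b) is provided: the mean of per-SNP ratios is
  Jensen-biased and does not converge to F.
* **Window estimators.** θ_π, θ_W, θ_H in a window centered on the focal
  SNP (default 30 kb, configurable; the window size behind the published
  −20..−80 H magnitudes is not recoverable, so absolute H magnitudes are
  treated as fixture data, not a recomputation target). θ_H and the π term
  of H use polarized sites only. Tajima's D uses the standard constants;
  D and H are NaN (never 0) on empty windows.
* **EHH / iHS.** EHH(x) = Σ_g C(c_g,2)/C(c,2) over haplotype groups from
  the core to x; iHH is the trapezoid integral outward in both directions,
  truncated where EHH < 0.05 or at the region edge (flagged).
  u = ln(iHH_ancestral/iHH_derived); cores need both classes ≥ 2 haplotypes
  and derived frequency in [0.05, 0.95]. Only sites with population MAF
  ≥ 0.05 refine the haplotype partition — haplotype scans are conventionally
  run on common (array-ascertained) variants, and very young private
  mutations would otherwise fragment exactly the young haplotype classes the
  statistic is designed to detect. Standardization: z-scores within
  equal-count derived-frequency bins (default 20; the validation study uses
  30 with ~3.5k pooled values); bins with < 2 values or zero variance leave
  members unscored. Physical bp is used throughout (no genetic map).

## Filter cascade

Stage 1: global F_ST > 0.3. Branch H: max pairwise F_ST > 0.5, then min
per-population H ≤ −20 + ε (ε = 1e−9). Branch iHS: max per-population
iHS > 2.0 (signed by default; an |iHS| switch exists because the published
inequality is written without absolute-value bars). Undefined statistics
fail their test rather than raising. The H boundary is inclusive because
the published candidate table contains a row with H = −20.000 exactly;
F_ST and iHS cuts are strict. Gene counts treat a multi-gene label
("A/B/C") as one label (a switch splits them). ΔDAF > 0.5 (any pair,
absolute value; all pairwise differences plus the max over pairs are
reported, since "global and population-wise" is ambiguous) and negative-D
(any population) are annotations, not filters. The published table's
counting rule behind its negative-D statement is unspecified, so the
package reports the flag count without asserting a target.

## Enrichment

Per-gene densities (SNPs/bp) for four region classes: Alu-hosted miRNA
targets, non-Alu miRNA targets, Alu without targets, full 3′UTR. Group
contrasts are per-gene-density Mann–Whitney tests (a pooled-count mode
exists behind a flag; the published choice is not stated). The exact MWU
p-value is computed by full enumeration of label assignments with midranks
when n_x + n_y ≤ 12, otherwise a tie- and continuity-corrected normal
approximation (scipy). The t contrast is Welch by default (pooled available).
No multiple-testing correction is applied anywhere; raw p-values are
reported with the number of comparisons.

The random-gene-set null draws sets of 30–35 genes matched to the test
set's longest-3′UTR-length profile across universe decile bins
(largest-remainder apportionment, sampling without replacement within
bins — "length normalized" is not further specified upstream, and decile
matching is deterministic and testable). The per-gene metric is summed per
set; the test set is flagged when its sum exceeds mean + 3·SD of the null
(sample SD, n−1). Calibration: under a null universe the flag fires in
≤ 2% of replicates (computed by the acceptance script).

## Synthetic data

* **Annotation generator.** Log-normal UTR lengths (median ~1.2 kb);
  Poisson(1) Alu copies per UTR as mutated copies (10% divergence) of a
  packaged 300-nt *synthetic* Alu-like consensus (GC-rich, fixed once; not
  a Repbase sequence — subfamily labels AluY/AluSx/AluJo are assigned
  round-robin for report realism). Exact 8mer seed complements are written
  into Alu or non-Alu positions with configurable probabilities after Alu
  insertion, so the truth table is exact. Each gene occupies its own contig
  at offset 0 on the + strand, which makes UTR and genomic coordinates
  coincide while still exercising the interval I/O.
* **Balding–Nichols panels.** Per SNP: p0 ~ U(0.05, 0.95); per-population
  frequency ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F) (exactly p0 at F = 0);
  independent haplotypes, no linkage. Defaults: 3 populations
  (CEU/CHB/YRI labels) × 100 diploids, 500 SNPs. Validates the
  frequency-based statistics and the density machinery.
* **Forward Wright–Fisher.** The ancestral population at the split is drawn
  at mutation–drift equilibrium with msprime (binary mutation model,
  continuous positions); the three daughter populations then evolve
  independently, forward in time: fitness-weighted Wright–Fisher resampling,
  Poisson crossovers, infinite-sites mutation, optional additive selection
  (1, 1+s, 1+2s) at the region midpoint introduced as a new mutation at an
  onset generation. A sweep run is sampled at the first generation the
  derived frequency crosses a target (default 0.88) — an *incomplete* sweep,
  where the H and iHS footprints are strongest; runs that lose the allele or
  never reach the target are re-simulated from an onset checkpoint with an
  incremented sub-seed.

  **Sweep study conditions** (`sweep_study_config`): 3 × 200 diploids
  (2N = 400 haplotypes per population), constant size, 200 kb, rescaled
  per-gamete rates μ = 5e−7/bp and r = 1e−7/bp, 200 post-split generations,
  s = 0.05 from generation 5. These values were chosen so that each
  statistic has its textbook behavior at desk scale: an equilibrium SFS
  (any contraction gives neutral windowed H a heavy left tail), a region
  long enough that the derived-class EHH integral is not edge-truncated,
  and enough segregating sites for multi-SNP windows. The simulations are
  ~100-fold rescaled relative to human parameters, so 2Ns = 20: the
  per-replicate sweep signal is moderate (|z| ≈ 2), and the 5-replicate
  median-versus-neutral-percentile contrasts in the validation study have
  moderate power at a random seed; the validation experiment therefore runs
  at fixed seeds, and single replicates should not be over-interpreted.

What the synthetic experiments do **not** show: performance on real
1000 Genomes-scale data (real sample sizes, demography, ascertainment, LD
structure), reproduction of the published genome-scale counts (which depend
on hg18/hg19 annotation snapshots and browser-precomputed statistics), or
miRanda/TargetScan site lists (the energy model and conservation scoring are
intentionally simplified away).

## Numerical conventions

Undefined statistics propagate as NaN and fail threshold tests rather than
erroring. Ties in overlapping-site selection break by score then leftmost
start. All generators and permutation tests take explicit seeds and derive
sub-seeds below 2^31; no global random state is touched. Window boundaries
are half-open `[center − w/2, center + w/2)`. Stage outputs are plain TSV;
reruns with the same config and seed are byte-identical.
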