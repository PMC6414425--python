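# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (`[start, end)`), the BED
convention; GTF input (1-based, inclusive) is converted on read. A
minus-strand gene's TSS is the exclusive `end` bound of its body — the
biological 5′ end under this convention, matching UCSC-style annotations.
Two intervals overlap when they share at least one base.

## Duplicate-read thresholding

PCR jackpots inflate the count of individual read signatures
(chrom, start, end, strand). The filter computes, per dataset (target and
spike-in reads together), the nearest-rank 95th percentile of the
per-signature occurrence counts — the `ceil(0.95·n)`-th order statistic,
floored at 1 — and trims signatures above it. Two behaviours are
available: the default **cap** keeps `threshold` copies of an
over-threshold signature (conservative: true high-occupancy positions
keep their strongest evidence), while **drop** removes the whole
signature group. Capping is idempotent: re-running removes nothing.

## Spike-in normalization

Exogenous (fly) chromatin is added in fixed proportion to cell number, so
spike-in reads measure effective sequencing depth per cell. Each target
read carries weight `10^6 / n_spikein`; the normalized depth is
`n_target / n_spikein × 10^6`. Per-gene signal is the weighted count of
target reads overlapping a 1-kb window centered on the TSS (clipped at
chromosome start). Multiplying all spike-in counts by *k* divides every
window signal by *k* exactly — the property the cross-condition
comparisons rest on.

## R-loop gene classification

The gene window runs from 1 kb before the TSS to 1 kb after the TES;
because the flank is symmetric this equals the body ± 1 kb for either
strand, clipped at 0. A gene is positive when ≥ 1 DRIP peak (unstranded)
overlaps its window. Among the initially positive genes, any gene whose
window overlaps another positive gene's window is reassigned
*uncertain due to proximity* — the shared signal cannot be attributed
unambiguously. The reassignment is a single pass over the initial
positive set: removing a gene from the positive pool cannot create new
window overlaps, so no fixpoint iteration is needed. An alternative
peak-based reading (uncertain only when a shared peak physically overlaps
both windows) is available via `proximity_basis="peak"`. Overlap queries
use an interval tree; tests check them against an all-pairs scan.

## Nascent transcription

Sense-strand RPKM = sense reads over TSS–TES / (length in kb × library
in millions). The library size counts mapped reads on both strands
("per million mapped" taken as strand-agnostic); a sense-only denominator
would roughly double every RPKM without changing ranks. Because bedGraph
coverage carries no read boundaries, reads are counted as the coverage
integral divided by the read length (a parameter; synthetic tracks keep
reads inside the gene body so the identity
`integral / read_length = read count` is exact and tested). Positivity is
strict: RPKM exactly 0.1 is negative. Rank-based top/bottom expression
classes take `floor(fraction × n_eligible)` genes each from the genes
negative for Polycomb marks, with ties broken by gene id for determinism.
Genes called uncertain-by-proximity are excluded from the
nascent × R-loop 2×2 table by default, since they belong to neither a
clean positive nor a clean negative set.

## Profiles and statistics

Meta-gene profiles average coverage in non-overlapping 10-bp bins across
windows centered on the TSS or TES (default flank 2 kb; the display
window is a presentation parameter). Minus-strand rows are flipped so
columns run 5′→3′. Bins beyond chromosome bounds are zero-filled and
masked out of column averages; bin sums × bin width conserve the window
coverage integral.

The Wilcoxon rank-sum test enumerates all C(n+m, n) rank assignments when
n + m ≤ 12 and the pooled sample is tie-free, returning the exact
two-sided tail probability of the rank-sum; otherwise it uses the normal
approximation with midranks, tie-corrected variance and a 0.5 continuity
correction. The approximation's worst-case deviation from the exact tail
is ≈ 0.09 at n + m = 4 and ≤ 0.05 from n + m = 8 — inherent to
approximating a 6-point discrete null with a continuous curve, and moot
in practice because enumeration covers that range. The t test is the
pooled-variance two-tailed unpaired Student test (Welch by flag), with a
guard for zero pooled variance; significance stars are `*`/`**`/`***` at
p < 0.05/0.01/0.001.

## qPCR percent input

`%input = 100 × 2^((Ct_input − log2(1/input_fraction)) − Ct_IP)`, the
standard dilution-adjusted ΔCt with amplification efficiency fixed at 2.0
per cycle (no standard curves are modelled). The quantity is invariant to
adding a constant to both Ct values, and composing it with the simulator
at zero noise returns the planted enrichment exactly for any dilution. No
IgG/background subtraction is applied. Group summaries report mean,
sample SD (n − 1) and n; comparisons report the fold change of means and
the t test above.

## Synthetic data: what it emulates and what it does not

The generator plants a genome of three gene classes — Polycomb-repressed,
highly active, inactive — with per-class R-loop probabilities
(defaults 0.25 / 0.76 / 0.05, mirroring the class structure reported for
mESCs), nascent-transcription rates, and ChIP enrichments. Defaults and
their rationale:

| parameter | default | why |
|---|---|---|
| gene length | 3–10 kb uniform | typical gene scale; long enough to hold a peak away from a close neighbour |
| min spacing | 3 kb | > 2 × flank, so isolated gene windows never touch |
| close-pair gap | 1–1998 bp | windows overlap by construction, bodies never nest |
| nascent rate (PcG) | 0.1 reads/kb | only ~40–50 % of the class has detectable nascent RNA, as run-on data show; identical for R-loop+ and R-loop− members |
| nascent rate (active / inactive) | 50 / 0.01 reads/kb | strong vs negligible transcription |
| ChIP enrichment (PcG / active / inactive) | 8 / 2 / 1 × background | EZH2-like occupancy pattern |
| background per TSS window | 20 reads | well-resolved per-gene medians at ~300 genes/class |
| RNase H1 depletion | 0.5 | planted halving of enrichment at R-loop-positive PcG genes |
| spike-in fraction | 0.1 | typical exogenous-genome share |
| duplication rate | 0.1 | geometric extra-copy law (failure-count convention), a simple heavy-tailed PCR-jackpot mimic |
| fragment length | 150–350 bp | sonicated-chromatin range; variable lengths keep accidental signature collisions negligible |

Spike-in reads live on a reserved `spike_*` chromosome namespace,
mirroring a combined-genome alignment; their expected count is fixed by
the experimental design (control-condition expected depth), not by the
realized per-condition read count, so normalization stays unbiased across
conditions.

The generator does **not** model sequence content, mappability or GC
bias, fragment-level overdispersion beyond Poisson, isoform structure, or
run-on assay dropout at weakly transcribed genes. Passing recovery tests
therefore demonstrates correctness of the computational pipeline under
idealized sampling noise, not robustness to the technical artifacts of
real libraries.

## Problem sizes, determinism, degenerate inputs

Recovery tests run at 300–2,000 genes per class on 2–4 synthetic
chromosomes of 5–50 Mb — large enough that binomial/Poisson sampling
error sits well below the planted effects, small enough that the full
suite and the acceptance script each finish in seconds. Every generator
draws from one `numpy` `Generator`; the pipeline threads a single seeded
stream through all stages and repeated runs are byte-identical.
Degenerate inputs (empty peak sets, zero library, zero spike-in, empty
gene classes, single qPCR replicates, zero pooled variance) raise typed
validation errors rather than silent NaNs; the one deliberate NaN — the
R-loop share among nascent-positive genes when none exist — comes with a
warning.

## Known limitations

- Whether the duplicate filter should cap excess copies or drop whole
  signature groups, and whether its threshold should use target-genome
  reads only, are judgment calls; both variants are implemented (`mode`,
  and the threshold is computed on the combined dataset by default).
- The RPKM library-size denominator (both strands vs sense-only) is
  likewise a convention choice; at fixed tracks the two differ only by a
  constant factor.
- Coverage-integral read counting is exact only when reads lie entirely
  within the integration window; real bedGraphs truncated at gene
  boundaries bias counts slightly downward.
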