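# Methods

## Scope and model

`splicepav` implements the downstream, matrix-level half of an
isoform-resolution splicing analysis. Its inputs are (i) a merged transcript
annotation in GTF (exon features with `gene_id`/`transcript_id`), (ii) an
isoform × sample FPKM matrix, and (iii) a sample table mapping each column to
(ecotype, age, treatment, replicate) with treatment ∈ {flight, ground}. All
read assembly, alignment and quantification are upstream of this package: it
consumes the quantified matrix as-is and applies no normalisation (zeros are
data, not missingness).

Two analyses share a fixed filter cascade — AS-parent-gene filter →
per-condition presence filter → (for dAS) TSS grouping → low-ratio filter →
permutation test — whose per-stage record counts are logged and written so a
run is auditable.

### Structural uniqueness and AS parent genes

Two isoforms of a gene count as distinct splice products when their ordered
intron chains (donor/acceptor junction pairs) differ; mono-exonic isoforms
are compared by their exon interval. Isoforms identical in intron chain but
differing only in terminal exon ends are *not* distinct — terminal-end
variation is an assembly artefact, not a splicing decision. A gene with ≥ 2
distinct structures is an AS parent gene; only its isoforms enter either
analysis. Transcripts without a strand are rejected outright because a
transcription start site is undefined without one.

### Presence/absence variation

An isoform is *present* in a condition iff min over that condition's
replicates ≥ τ, with τ = 10 FPKM inclusive by default (a replicate exactly
at 10.0 is present; 9.999 is not). The rule deliberately trades sensitivity
for confidence: one failing replicate vetoes presence. "Absent" is defined
purely as failure of this criterion — no second, lower threshold is imposed
— and reports carry the caveat that absent isoforms may merely be lowly
expressed. τ is configurable for sensitivity analyses. Flight-only /
ground-only / common sets are plain set algebra over the per-condition
present sets; multi-set comparisons are reported as exact Venn regions
(2^k − 1 counts partitioning the union). Because the question "which
isoforms does a comparison gain or lose" can be read per condition either as
exclusive-present or all-present, the overlap table reports both, labelled.

### Isoform ratios and the dAS test

Within a TSS group (same gene, same chrom/strand, identical strand-aware 5′
coordinate; matching is exact by default, with an optional merge window) the
default ratio of member *i* in a condition is its condition-mean FPKM over
the group total (`condition-mean` mode). A `per-replicate-mean` mode —
ratios formed within each replicate, then averaged, skipping replicates with
zero group total — is available because the choice between the two is a
genuine modelling ambiguity; both are exposed and the default is the
condition-mean form, which matches how per-condition ratio bar charts are
usually presented.

Members with ratio < ε in **both** conditions (ε = 0.01, strictly below;
0.01 exactly is retained) are removed. Reported ratio vectors are *not*
renormalised after this removal, so reported shares stay comparable to the
raw per-condition composition; the test statistic, however, is computed on
the renormalised surviving members so its inputs are probability
distributions. Groups reduced below two members are dropped; groups whose
total expression is zero in exactly one condition are excluded from testing
and counted separately (`pav_like_groups`) — an all-or-nothing difference is
a presence phenomenon, already handled by the PAV analysis.

The statistic is √JSD with log base 2:

    JSD(p, q) = ½ KL(p ‖ m) + ½ KL(q ‖ m),  m = ½(p + q)

so the statistic lies in [0, 1], is 0 iff p = q, and is a metric
(symmetry and the triangle inequality are property-tested). Implementation
handles 0·log 0 = 0 by continuity; inputs must sum to 1 within 1e−9.

Significance comes from permuting which replicate columns carry the flight
label within the comparison pair, recomputing ratio vectors and √JSD per
assignment. With n_f + n_g replicates and C(n_f+n_g, n_f) ≤ 10 000
assignments (70 for the default 4 + 4) the enumeration is exhaustive and
p = #(assignment statistic ≥ observed)/#assignments — the true labelling is
included, so p > 0 always. Larger designs fall back to Monte-Carlo sampling
with the +1-corrected estimate p = (1 + #≥obs)/(1 + n_perm), deterministic
given the seed. Assignments whose statistic is undefined (zero pseudo-
condition total) count toward the numerator, which is conservative.
Benjamini–Hochberg FDR runs across all tested groups of one comparison
pair; a gene is dAS when any of its groups has q ≤ α (α = 0.05 default),
and a dominant-isoform switch is flagged when the ratio argmax differs
between conditions.

### Resolution limits of the 4-vs-4 permutation null

√JSD is symmetric, so every label split ties its complement and the
exhaustive 4v4 p-value is supported on multiples of 2/70 ≈ 0.0286. Two
consequences, both verified in the test suite:

- **Conservativeness.** At nominal α = 0.05 the achievable level is
  2/70 ≈ 2.9%: the test can only under-reject. Calibration against the
  nominal level is therefore measured at 6 + 6 replicates, where the grid
  resolves it (closest achievable level 46/924 ≈ 4.98%); the 4v4 design is
  asserted never to be anti-conservative.
- **An FDR cliff.** A block of b groups at the p-floor receives
  q = (2/70)·m/b under BH with m tested groups, so q ≤ 0.05 requires
  m/b ≤ 1.75. With ~10 genuinely switching groups, at most ~7 null groups
  may survive the presence filter alongside them; whether a true switch
  crosses q ≤ 0.05 can therefore depend on how many null groups happen to
  be testable, even though every true switch sits at the smallest p the
  design can produce. This is an information limit of four replicates per
  arm (70 splits), not a power deficit of the statistic; the acceptance
  script reports both the q-based recovery and the fraction of planted
  groups at the p-floor so the two are distinguishable.

## Synthetic-data generator

The generator emulates the emulated experiment's layout: 2 ecotypes × 2
ages × {flight, ground} × 4 replicates (32 samples), genes carrying 1–4
isoforms with a configurable chance of sharing their gene's TSS. Isoform
structures differ by skipping distinct internal exons, so structural
uniqueness holds by construction and the AS-gene detector finds exactly the
multi-isoform genes. Key parameters (defaults chosen once, as realistic for
plant RNA-seq at this depth):

| parameter | default | meaning |
|---|---|---|
| `isoform_count_weights` | {1: .55, 2: .25, 3: .12, 4: .08} | most genes assemble 1–2 isoforms |
| `shared_tss_prob` | 0.6 | chance a gene's isoforms share one TSS |
| `baseline_log_mean/sd` | 1.1 / 1.5 (natural log) | log-normal FPKM, median ≈ 3, wide spread |
| `noise_log_sd` | 0.2 | ≈ 20% replicate-level CV, multiplicative |
| `pav_fraction`, `pav_high/low` | 0.05, 50 / 1 FPKM | planted condition-exclusive isoforms per pair |
| `switch_fraction` / `n_switches` | 0.08 | planted dominant-isoform switches per ecotype |
| `switch_displacement` | 0.5 | dominant-minus-runner-up ratio gap, swapped between treatments |
| `tau` | 10 | presence threshold the guard band is built around |

Planted switch groups swap the two leading members' shares between
treatments ((share+δ)/2 ↔ (share−δ)/2, any further members fixed at 0.1),
preserving the group total, which is drawn high enough that every member
clears the presence band. Ecotype-specific switch gene sets are drawn
independently with a small forced overlap (10%, minimum one gene), so the
demo dataset reproduces the qualitative pattern of largely ecotype-specific
splicing responses. Replicate noise is multiplicative log-normal.

**Guard band.** Baseline expression values landing within
(τ/e^{5σ}, τ·e^{5σ}) of the presence threshold (σ = `noise_log_sd`) are
pushed to the nearest band edge, and planted PAV levels are validated to
clear the band. This makes presence calls deterministic given the planted
truth — the planted-recovery tests demonstrate *correct set logic and
filtering*, with 100% precision/recall by construction. Real data have no
guard band: isoforms genuinely near τ will flip presence calls between
replicates and conditions, so perfect recovery on these simulations says
nothing about borderline-expression behaviour on real matrices. Library-size
effects, gene-length bias, count-level sampling noise and correlated
replicates are likewise not simulated; the analysis consumes FPKM, so
simulation happens directly at FPKM level.

## Numerical and edge-case choices

- Coordinates are GTF convention throughout (1-based, inclusive); TSS is the
  strand-aware 5′ coordinate (first exon start on `+`, last exon end on `-`).
- Ratio vectors must sum to 1 within 1e−9; statistic comparisons in the
  permutation count use a 1e−12 slack so the true labelling always counts.
- Presence threshold comparisons are inclusive (≥ τ); ratio-filter
  comparisons are strict (< ε): both boundaries are covered by tests.
- Degenerate inputs fail loudly: strandless transcripts, exonless
  transcripts, duplicate ids, matrix/metadata mismatches, negative or
  non-finite FPKM, singleton groups passed to the permutation test.
- Problem sizes in the tests and acceptance script (500 genes for the full
  design, 210 genes for the power study, 500 null groups for calibration)
  keep every study a few seconds long while leaving dozens of tested groups
  and >100 planted events per study.

## Known limitations

- The dAS statistic is this package's own divergence-plus-permutation
  construction over the same conceptual quantity (TSS-grouped relative
  isoform abundance); it is not a reimplementation of any assembler's or
  differential-expression tool's splicing test, and makes no claim to
  reproduce such calls on real data.
- Exact TSS matching assumes the upstream merge assigned shared TSSs
  identical coordinates; ragged 5′ ends require the optional merge window.
- Four replicates per arm bound the permutation p from below at 2/70; see
  the resolution-limit discussion above before interpreting FDR-adjusted
  calls from small designs.
- AS event-type classification (exon skipping vs intron retention etc.),
  gene-level differential expression and enrichment analyses are out of
  scope.
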