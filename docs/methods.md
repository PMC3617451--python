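# Methods

## Overview

`medusa` compares MeDIP-seq fragment counts between two cohorts of
replicated libraries in fixed genomic windows under a negative-binomial
model, merges significant windows into differentially methylated regions
(DMRs), and validates calls against bisulfite data and reference interval
sets.  MeDIP coverage is an enrichment signal, monotone in methylated-CpG
content but not an absolute methylation level; everything downstream is
therefore built on *relative* count comparisons.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED-native).  Wig output
converts to 1-based fixedStep on the way out; GFF input converts from
1-based closed on the way in.  Nothing else touches the convention, which
avoids off-by-one drift across the stages.

## Fragment filtering

A fragment is the insert `[min(read starts), max(read ends))` of a proper
read pair.  Pairs are removed when not proper, or when *neither* read
reaches the alignment-score threshold (default 10 — removal requires both
reads to fail).  "Alignment score" is the score column the aligner stores
(MAPQ for BAM input); the threshold is configurable.  Duplicates are
defined by identical chromosome/start/stop — strand intentionally does not
enter the key — and the first-encountered fragment is kept, which is
deterministic for coordinate-sorted input.  The fragment's strand is the
strand of read 1: in a paired-end MeDIP library the first read is sequenced
from the immunoprecipitated strand, so it is the natural carrier of the
strand-of-origin signal.  This choice is a convention (configurable at the
call site), not a claim about every library chemistry.

## Fragment-length normalisation

Length bias arises during immunoprecipitation, so trimming aligned
fragments cannot correct it; removal (sub-sampling) can.  Given per-sample
length histograms on a common grid (default bin width 5 bp — 1 bp grids
are noisy at realistic library sizes), the target distribution is the
per-bin minimum of the samples' proportions, renormalised.  This is the
maximal distribution dominated by every sample, i.e. the choice that
removes the fewest fragments; it is one deliberate choice among several
defensible ones and is isolated behind `target_distribution` so it can be
swapped.  Each sample retains `n_s = floor(min_l c_l / q_l)` fragments
(the largest total at which every bin can be filled), `round(n_s·q_l)` per
bin (round-half-even), drawn uniformly without replacement from a named,
seeded generator; rounding residues are corrected on the largest target
bins, deterministically.  After joint normalisation the maximum pairwise
two-sample KS statistic is bounded by `2/min(n_s)` plus the bin-resolution
term, which the acceptance suite verifies.

## Window counting and QC

Fragments are assigned to windows by midpoint ("point data"), so with
non-overlapping tiles window counts sum exactly to the library size.  A
per-base overlap count is available for track rendering where pileup is
more faithful.  Replicate agreement is the Pearson correlation of RPM
values over 500 bp windows sliding in 250 bp steps, keeping windows whose
combined raw count is at least 5; the threshold applies to the *sum* of
the pair's counts (a per-sample variant is available).  Correlations are
computed on RPM by default with a log2(x+1) option; an undefined
correlation (fewer than 2 qualifying windows, or zero variance) is
returned as an explicit `None`, never silently 0.  Saturation curves split
the library into random halves and correlate growing subsamples of one
half against the other.

## The differential test

* **Depth filter.**  Windows with combined raw depth below 10 over all
  samples are removed before testing (and counted).
* **Size factors.**  Median over all-positive windows of the ratio of a
  sample's count to the window's geometric mean.  Robust to a minority of
  differential windows; fails loudly when no window is positive in every
  sample.
* **Dispersion.**  With normalised counts `x_ij = k_ij / s_j`, per-window
  pooled mean `q_i` and within-cohort pooled variance `v_i`, the raw
  method-of-moments dispersion is `α_i = max(0, (v_i − q_i·ξ)/q_i²)` with
  `ξ = mean(1/s_j)` — the excess of observed variance over shot noise on
  the scale `var = μ + αμ²`.  A lowess regression of raw α on log q
  (frac 0.3, 2 robustness iterations, interpolated linearly in log-mean
  space, floored at 10⁻⁸) shares information across windows; the test
  uses `max(raw_i, fitted(q_i))`.  This "maximum" sharing is deliberately
  conservative for the 2–3 replicate designs the pipeline targets;
  "fit-only" is available.  With no replicated cohort the fit falls back
  to pooled across-cohort variance with a warning.
* **Exact conditioned test.**  Cohort count sums `k_A`, `k_B` with summed
  size factors `s_A`, `s_B`: under NB laws with means `q̂·s_A`, `q̂·s_B`
  and common dispersion α, conditioning on `k_S = k_A + k_B` gives
  `p = Σ{P(a)P(b) : a+b = k_S, P(a)P(b) ≤ P(k_A)P(k_B)} / Σ{P(a)P(b)}`.
  α = 0 is evaluated as the Poisson limit (conditional law Binomial).
  The sum is evaluated by full vectorised enumeration of all `k_S + 1`
  splits — exact at any desk-scale total.  Ties are compared with a
  relative tolerance of 10⁻¹² to guard float noise on mathematically
  equal splits; the tolerance is far below the enumeration-agreement
  bound the acceptance suite enforces.  p is clamped to (0, 1].
* **Fold change.**  `log2((k_B/s_B + 0.5)/(k_A/s_A + 0.5))`; the 0.5
  pseudo-count is display-only and never enters the test.
* **Multiplicity.**  Benjamini–Hochberg over all tested windows.
* **Merging.**  Runs of windows with adjusted p ≤ 5% and a shared
  fold-change sign are merged, tolerating up to 1 non-significant (or
  depth-filtered) window slot inside a run; the gap allowance is a free
  parameter with no canonical value, and 1 keeps regions from fragmenting
  on single noisy windows without bridging unrelated signals.  A region's
  best window is its minimum-p member (ties → leftmost) and the region
  FDR is that window's adjusted p; no region-level recombination of
  p-values is attempted.

## Strand asymmetry

Within a region, fragment strand-of-origin counts (f, r) by midpoint give
a forward fraction and a two-sided exact binomial p against 0.5.  A region
is flagged as a non-CpG-methylation candidate when p < 0.01 *and* the
majority strand carries ≥ 80% of fragments — the effect-size condition
prevents flagging large regions with trivial imbalances.  Both thresholds
are configurable.

## Annotation

Feature overlap counts union base pairs (features merged first, so
overlapping annotation entries are not double-counted).  Classification
takes the highest-priority feature with ≥ 1 bp overlap; the default
priority CpG island > promoter > exon > intron, with intergenic fallback,
is explicit configuration, not a claim of a canonical partition.
Promoters default to TSS −1000/+500 bp.  Nearest-gene association is
strand-aware: a gene is a candidate if the DMR overlaps its span extended
10 kb upstream of the TSS and 5 kb past the 3′ end; the minimal distance
to the gene body wins (0 inside).

## Bisulfite validation

CpG calls with depth < 10 are removed; the two samples' score vectors on
the shared CpG set are quantile-normalised (two-sample flavour: each value
replaced by the mean of the two samples' order statistics at its rank,
ties by average rank), removing global-methylation offsets.  DMRs with
fewer than 10 qualifying CpGs or any simple-repeat overlap are excluded —
repeats and non-CpG methylation produce MeDIP signal invisible to CpG
bisulfite calls.  Δms is the unweighted mean per-CpG difference
(cohort A − cohort B; a depth-weighted option exists); a hyper DMR
(B above A in MeDIP) is *supported* by Δms < 0 and a hypo DMR by Δms > 0.
Empirical p-values use the add-one estimator `p = (1 + #{null beyond
observed})/(n_perm + 1)` at 1,000 permutations, which never returns 0 and
matches the "p < 0.001" reporting convention.

## Observed/expected overlap

For two interval sets, observed overlap is the base-pair intersection of
their unions; the expectation under independent uniform placement is
`bp_a · bp_b / genome_bp` (the global formula — chromosome-level structure
is not modelled).  The null distribution of O/E comes from sets of random
500 bp regions, placed with chromosome probability proportional to length
and uniform starts, without overlap-rejection (duplicates are possible at
tiny probability and harmless to the union-based statistic).

## The simulator

The generator emulates the study design the pipeline targets: two cohorts
× 3 replicates, ~2×10⁵ fragments per sample, a 1 Mb single-chromosome
genome, 100 planted 4-fold 500 bp DMRs.  Its components:

* **Genome** — CpG islands (default 1% of the genome in 1 kb islands,
  placed uniformly without overlap) and Bernoulli per-base CpG starts
  (rate 0.1 inside islands, 0.01 outside — the ballpark of mammalian
  genomes).
* **Methylome** — per-base levels: background 0.8 (methylated), islands
  0.1 (largely unmethylated).  A planted hyper-in-B region lowers cohort
  A to `0.8/fold` while B keeps 0.8; hypo regions mirror this.  Levels
  stay in [0, 1] and the emission ratio approximates the fold.
* **Fragments** — length uniform on the sonication range 50–350 bp
  truncated to the size-selection window 150–200 bp.  An anchor base is
  drawn with weight `ε + level(x)·cpg(x)` (ε = 2×10⁻⁴ per bp, small
  enough that CpG signal dominates background) and the fragment is placed
  uniformly over positions covering the anchor, making a fragment's
  weight proportional to its background-plus-methylated-CpG content —
  the simplest law under which coverage is monotone in methylation.
  Antibody saturation and CpG-density non-linearities are deliberately
  not modelled.  Strand is forced inside planted asymmetric regions
  (looked up at the fragment midpoint) and fair-coin elsewhere.
  Optional per-tile Gamma(1/α, α) multipliers create NB overdispersion
  between replicates.
* **Bisulfite calls** — per CpG, depth ~ Poisson(mean 30) and methylated
  count ~ Binomial(depth, level).

The Δms concordance harness plants 2 kb DMRs rather than 500 bp ones: at
the background CpG rate of 0.01/bp a 500 bp region carries ~5 CpGs and
would be removed by the validation pipeline's own ≥ 10-CpG filter, so the
wider regions are what make the validation stage exercisable end-to-end
(real DMRs span 500 bp windows up to tens of kb).

All randomness flows from one seed per run through spawned child streams.

What passing tests on this simulator do *not* show: robustness to
copy-number variation, GC/mappability bias, antibody batch effects,
repeat-driven multi-mapping, or real inter-replicate biological
heterogeneity beyond the NB overdispersion model.  Null false-discovery
behaviour is assessed on direct NB count simulations (both cohorts the
same gamma-Poisson law, α = 0.2), which isolates the statistical engine
from the fragment model.

## Problem sizes and numerical choices

The test and acceptance runs use 1 Mb genomes, 10,000-window null
matrices, 20-seed averages for stochastic quantities, and 1,000
permutations for overlap statistics — sizes at which every stochastic
check has comfortable Monte-Carlo resolution while the full suite runs in
minutes on one CPU.  Degenerate inputs fail loudly rather than silently:
empty length support, zero library sizes, gapped window grids, no
all-positive window for size factors, undefined correlations and
zero-fragment regions all raise or return explicit `None` markers.

## Known limitations

* The exact test assumes a common dispersion for both cohorts at a
  window; strongly cohort-specific variance is not modelled.
* Size factors assume most windows are non-differential; global
  methylation shifts violate this (the bisulfite quantile normalisation
  addresses the analogous bias on the validation side only).
* Region FDR is the best member window's adjusted p, not a region-level
  recombination.
* GLM-style shrinkage estimators, covariate designs beyond two cohorts
  and CNV-aware normalisation are out of scope.
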