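# Methods

`plasmacall` implements a targeted liquid-biopsy analysis stack: UMI-consensus
error correction of paired amplicon reads, local alignment against amplicon
references, whitelist-screened variant tabulation, and a specificity-anchored
multi-cancer classifier with its evaluation statistics. This note records the
model and procedure behind each stage, the parameters that matter, and the
design choices made where the design was genuinely open.

## Read model and consensus calling

The assay structure assumed throughout: read 1 begins with a gene-specific
primer followed by genomic sequence; read 2 begins with a unique molecular
identifier (UMI) attached before amplification, followed by the reverse
complement of the far end of the molecule. All read pairs sharing a
(primer target, UMI) key are presumed PCR/optical copies of one original
cfDNA molecule.

Processing steps and their tunables (`EngineConfig`):

- **Primer screen.** The read-1 prefix is matched against every panel primer
  allowing substitutions only (amplicon prefixes are fixed-position, so
  indels in the primer region are not modelled). Default tolerance
  `max_primer_mismatches = 2`; a tie at the minimum distance rejects the read
  as `ambiguous_primer` rather than guessing.
- **UMI clip.** The first `umi_length` bases of read 2 (default 12, the
  common length for this library chemistry) are the family key. `umi_length
  = 0` is a supported degenerate mode (every read on a target forms one
  family) used in tests.
- **Pair merge.** Read 2 is reverse-complemented and slid along read 1
  looking for the longest ungapped overlap with at least `min_overlap = 20`
  bases and a mismatch fraction at most 0.1. Inside the overlap read-1 bases
  win unless their Phred quality is below `q_low = 20` while the read-2 base
  is at or above it; read 2 extends the merged molecule beyond read 1's end.
  Pairs with no acceptable overlap keep read 1 alone by default
  (`unmerged_policy = "keep_read1"`); a `reject` policy is available since
  either behaviour is defensible and the right choice depends on insert-size
  distribution.
- **Consensus.** Per column over the family's merged sequences, the modal
  base is taken when its fraction among covering members is at least
  `min_agreement = 0.75`, otherwise `N`; a tied mode is also `N` — the
  consensus never invents a base. Families smaller than `min_family_size = 3`
  are rejected (`small_family`), as are fragments with more than
  `max_n_fraction = 0.10` ambiguous positions. These are standard
  UMI-consensus settings; all are surfaced because no canonical values exist.
- Optional directional UMI merging (1-mismatch neighbour absorbed when the
  larger family has at least twice-minus-one the reads) is off by default:
  at amplicon depths the collision risk of 12-base UMIs is low and exact
  grouping is the more conservative choice.

Every input pair is accounted for exactly once across `consensus_member` and
`rejected:<reason>` tallies; tests assert this conservation.

## Alignment and variant extraction

Each consensus fragment is aligned to its amplicon reference with an
affine-gap Smith–Waterman (Gotoh) algorithm. A gap of length L costs
`gap_open + (L-1)·gap_extend`; the default scheme (match 2, mismatch −3,
gap open −5, gap extend −2) is a conventional short-read setting and fully
configurable. The dynamic program is exact; the recurrence is JIT-compiled
(numba) and the traceback runs in Python. Among co-optimal alignments the
implementation prefers the smallest reference start, then smallest query
start, then fewest gap openings, resolved over co-optimal end cells; within
one traceback gaps close eagerly. A test battery checks score equality
against an independently written plain-Python DP on random instances.

Variant events come from walking the alignment operations:

- maximal runs of adjacent substitutions merge into one MNP (a single
  substitution is a SNP); substitutions are never merged with indels;
- insertions and deletions are anchored on the preceding reference base and
  left-normalized against the amplicon so that every equivalent
  representation collapses to one canonical key (the same normalization the
  whitelist is validated against);
- columns where the fragment has `N` produce no call; events spanning 50 or
  more bases are discarded (the assay targets short variants only);
- only keys present on the panel whitelist become observations; everything
  else is counted in a diagnostics channel so callable-but-unlisted signal
  remains visible without entering the mutation table.

Fragments whose best local alignment covers less than 80% of the fragment
are dropped as unalignable; this guards the coverage denominator against
chimeric molecules. The threshold is a package choice — nothing forces 80% —
and is deliberately permissive since simulated fragments align end-to-end.

## Mutation table and QC

For each unique variant key: `count` = distinct consensus fragments carrying
the variant, `coverage` = distinct fragments whose alignment overlaps the
variant's (left-normalized) start position, `frequency` = count/coverage ×
100 (percent). Counting happens after UMI collapsing — frequencies near 0.1%
are only meaningful in molecule space, not raw-read space; the raw-read
alternative would conflate PCR duplication with molecular support. Zero-count
whitelist variants are absent from the table and imputed as 0 when feature
matrices are built, keeping tables sparse.

Sample QC: mean consensus coverage across the selected targets (default: all
targets, averaged over whitelist positions) must not fall strictly below the
threshold (default 200); a mean of exactly 200 is retained. The strictness
of the inequality is load-bearing and tested at the boundary.

## Classifier and operating points

Features are the per-sample whitelist frequencies (percent), zero-filled,
rows and columns sorted. Each sample is scored by a random forest trained on
all other samples (leave-one-out cross-validation); fold *i* uses random
state `seed + i` over the canonical sample order, which makes score sets
reproducible and invariant to input row permutation. Defaults: 100 trees,
square-root feature subsampling, class-balanced weights. 100 trees keeps a
full LOOCV sweep tractable on one core while leaving the cross-validated
AUC of every scenario in this repository unchanged within seed noise;
ensemble size, like every other hyperparameter, is surfaced in
`ModelConfig`. K-fold cross-validation is available as an escape hatch for
large synthetic cohorts.

Cohort subsetting mirrors the study protocol: the full model uses all
cancers and all controls; an organ model uses that organ's cancers and all
controls; the prostate and breast models restrict both groups to males and
females respectively; manual and automated DNA-extraction batches are never
pooled (the CLI refuses mixed batches without `--allow-mixed-batch`).

Operating points are anchored on controls only: candidate thresholds are the
midpoints between sorted distinct control scores plus sentinels, a sample is
positive strictly above the threshold, and the cutoff whose achieved
specificity is *nearest* the target (95% or 99%) wins, ties toward higher
specificity. The nearest rule, rather than "at least", is deliberate: with
415 distinct control scores it marks 21 controls positive (achieved 94.94%)
where an "at least 95%" rule would mark 20 — and 21/415 is the behaviour this
stack is calibrated to reproduce.

## Evaluation statistics

- **Sensitivity CI.** Wald interval with z = 1.96 computed on the *rounded*
  sensitivity percentage, bounds rounded (half away from zero) and clipped
  to [0, 100]. This convention reproduces the full set of published-style
  cells exercised in the tests; the exact-proportion Wald differs in
  specific cells (e.g. 28/66 gives a lower bound of 31 instead of 30) and is
  available via `on_rounded=False`. One published all-cancers cell (150/260
  printed as 57%) is arithmetically inconsistent with nearest rounding
  (57.69 → 58) and is therefore documented here rather than asserted.
- **AUC** via the Mann–Whitney rank statistic with ties counting one half,
  verified against a brute-force pair-counting oracle.
- **Stage rows**: per-stage detection at the 95% operating point plus a
  per-stage AUC (stage's cancers vs all controls); cancers of unknown stage
  appear in no row.
- **Rank screens**: Kruskal–Wallis omnibus (tie-corrected); pairwise
  Wilcoxon rank-sum post hocs (normal approximation, tie-corrected, no
  continuity correction, no multiplicity adjustment) run only when the
  omnibus p < 0.05. Identical group multisets give a pairwise p of exactly 1
  under this approximation. The omnibus statistic is undefined when every
  observation across all groups is identical; that degenerate case reports
  p = 1.
- **False-positive audit**: controls above the threshold with score and
  margin, sorted by descending score, count consistent with the operating
  point.

## Synthetic data: what it emulates and what it does not

**Read level.** Per target, template molecules are drawn; each independently
carries each spike-in variant with probability equal to its VAF; each
molecule expands into a read-pair family whose size follows a zero-truncated
Poisson (mean 6, a realistic family-size spectrum at desk scale);
substitution errors are iid and uniform over the three alternatives at a
configurable per-base rate (default 0.005). Indel sequencing errors are off
by default so consensus tests stay crisp — indel *calling* is still
exercised through spiked insertions/deletions. The documented reference
scale is ~200,000× raw depth over ~3000 targets; desk-scale defaults (≤
5,000 molecules per target, 200-variant panels) preserve the per-molecule
structure while keeping simulations tractable. Not modelled: fragment-size
distributions, GC bias, strand/duplex structure, index hopping, quality
degradation along the read.

**Cohort level.** Background frequencies are zero-inflated exponential
(default: 30% zeros, mean 0.05%). Each cancer multiplies 5 signal variants —
drawn from a 5-variant shared pan-cancer hotspot pool plus a 2-variant
organ-private pool — by `effect_size` times a per-stage multiplier. The
shared/private pool split mirrors how recurrent-variant panels work in
practice: a handful of pan-cancer hotspots carry most of the signal, with
organ-enriched sites adding specificity. Because the zero-inflation
Bernoulli is shared between background and signal cells, `effect_size = 1`
reduces *exactly* to the control distribution, which is what makes the null
calibration test meaningful. Sex is consistent with organ (prostate male,
breast female). Not modelled: real mutation co-occurrence, clonal
hematopoiesis artefacts, age effects, batch effects beyond the label.

Passing tests on these simulations demonstrate that the pipeline recovers
what it is told is there (down to 0.1% VAF over 20,000 molecules), that the
classifier finds planted multiplicative signal and scores exactly at chance
when none exists, and that the operating-point machinery lands where the
arithmetic says it must. They do not demonstrate clinical performance: the
study cohort is not public, so the published clinical sensitivities and AUC
are replaced by these structural checks, and the simulators make no claim of
biological realism beyond the structure above.

## Numerical choices and degenerate inputs

- Frequencies are serialized with 6 significant digits and re-validated
  against count/coverage × 100 on read.
- Rounding everywhere is nearest integer, half away from zero.
- Consensus columns with no covering votes (all-`N` voters) are `N`.
- An empty alignment query yields score 0 with no operations; an empty
  reference is an error.
- The read simulator applies errors to the UMI as well; the resulting rare
  family splits are part of the modelled reality (a split family usually
  fails `min_family_size` and is counted, never silently lost).
- Problem sizes in the test suite (e.g. four targets × 2,400 molecules for
  the error-suppression measurement, 20,000 molecules for the low-VAF
  recovery, 10-seed calibration sweeps at 40–60 samples per class) were
  chosen to give each statistical check comfortable resolution at desk
  scale.

## Known limitations

- Consensus is column-anchored at the primer-trimmed start; families whose
  members disagree by indels early in the molecule will consense poorly and
  surface as `N`-heavy fragments (counted, not called). Alignment-based
  (indel-aware) family consensus is out of scope.
- The Smith–Waterman is the mathematical optimum, not a banded/SIMD
  implementation; throughput is adequate for amplicon-length references
  only.
- Tissue-of-origin prediction is explicitly not attempted.
- The QC subcommand of the CLI approximates per-target coverage from the
  mutation table when run file-to-file; the exact per-target rule is
  available in-process (`qc_filter` on tables that carry
  `per_target_mean_coverage`).
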