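# Methods

This note documents the models, algorithms and numerical choices behind
`ampliclass`, in the order data flows through the pipeline: synthetic cohort
and read generation, read curation (QC), taxonomic binning, abundance
tables and diversity, association statistics, and supervised
classification. It also states what the synthetic generator does and does
not emulate, and therefore what passing tests demonstrate about real data.

## Synthetic cohort model

A cohort is a taxa-by-sample count table with class labels. Per sample:

- **Composition.** Proportions are drawn from a Dirichlet distribution with
  a shared concentration vector α. The default baseline is a power law,
  α_i ∝ 1/(i+1), scaled to a total concentration of 300. The power-law
  shape gives a few dominant taxa and a long tail: with 200 taxa, ~90% of
  taxa sit below 1% mean relative abundance, matching the observation that
  many informative taxa in gut surveys are rare. The total concentration
  sets between-sample (biological) variability — a 1% taxon has a
  between-sample CV of roughly `1/sqrt(α_i)` ≈ 0.6 at the default. This
  value was calibrated once so that the package's reference detection
  conditions hold: ten planted effects of |log2 fold change| = 1.5 at 60
  samples per class and ~2690 reads/sample are recoverable (≥8/10 at
  q<0.05) and support a cross-validated AUC ≥ 0.9. Lower totals (e.g. 50)
  make the same effects statistically invisible at that design.
- **Planted effects.** Disease effects are planted on the simplex: in the
  case class the proportions of the chosen taxa are multiplied by `2**lfc`
  and the vector is renormalized. This preserves compositionality; because
  the planted taxa are a small fraction of total abundance, the realized
  case/control abundance ratio for `lfc = 1` is ≈ 2 (the renormalization
  bias is a few percent).
- **Depth.** Sequencing depth is negative binomial with mean 2690
  reads/sample and dispersion (size) 9. The dispersion reproduces a
  standard deviation of ≈ 900 reads at that mean, consistent with the
  ~2690 ± 900 spread typical of multiplexed 454 runs. The published figure
  is a median ± MAD; mapping it onto a generative distribution is a
  modeling choice, and the overdispersed negative binomial is the standard
  one for per-sample read yields.
- **Diversity gradient.** An optional per-class multiplier on α models the
  loss of community diversity in severe disease: multipliers < 1 make
  Dirichlet draws spikier, lowering expected Shannon diversity without
  changing expected composition.
- Counts are multinomial given proportions and depth; everything is
  deterministic given the spec's seed.

## Synthetic reads

The read simulator turns a cohort into a multiplexed pool as a 454-style
amplicon run would produce it. Each read is

    barcode + forward primer (357F) + template substring + reverse primer (926R)

with the template drawn from the reference sequence of the read's genus
(cohort taxon *i* maps to the reference's *i*-th genus), uniform template
length in a configured range (default 300–450 nt), optional per-base
substitution errors, and per-base Phred qualities drawn from a normal
distribution (default mean 35, sd 4, clipped to [2, 41]). IUPAC-degenerate
primer positions are instantiated randomly per read.

A configurable fraction of reads is deliberately corrupted to violate
exactly one QC rule each — truncation below the length floor, extension
above the ceiling, low mean quality, an ambiguous base, a one-substitution
barcode (checked not to collide with any valid barcode), or five
IUPAC-aware mismatches planted in the reverse primer. The defect label is
embedded in the read id, so QC accounting can be audited read by read.
`designed_defect_fixture()` provides a fixed ten-read instance (four clean,
six single-rule violations, plus a passing read at the four-mismatch
boundary).

**What the generator does not emulate:** 454 homopolymer indel errors,
chimeras, quality decay along the read, phylogenetically realistic
reference sequences (genus backbones are independent random sequences, so
genera are more separable than real 16S genera), and covariance between
taxa beyond what the Dirichlet induces. Passing tests therefore demonstrate
correctness of the machinery and calibration of the statistics under a
known model — not classifier performance on real cohorts, where taxa are
harder to separate and effects are weaker.

## Read curation (QC)

Reads are demultiplexed by exact 5' barcode match (barcodes must be
prefix-free; the barcode is trimmed on assignment), then filtered in a
fixed order, recording the first violated rule:

1. length < 200 nt or > 600 nt (evaluated on the read as given, before
   primer trimming; a switch moves the check after trimming);
2. mean Phred quality < 25 — the threshold is strict, a mean of exactly 25
   passes. The aggregate is the plain mean over the read; a read with no
   quality data under a quality-requiring policy is an error, not a pass;
3. any non-ACGT character;
4. more than 4 mismatches to the reverse primer. The primer is located as
   the best-scoring ungapped placement within the final 1.5 ×
   primer-length window (rightmost placement wins ties). Mismatch counting
   honors IUPAC degeneracy on the primer side only (M matches A or C, R
   matches A or G, …); an N in the read matches nothing. The forward
   primer is not a rejection rule; it is trimmed when it matches the 5'
   end within 2 mismatches.

Passing reads have primers trimmed. Filtering is idempotent: a read marked
passed is returned unchanged. Chimera detection is delegated to external
tools; `apply_chimera_report` rejects reads listed in a report file and
logs unknown ids without failing. On every run, passed + rejected counts
equal the input count exactly.

## Taxonomic binning

Classification is a word-based naive-Bayes classifier over 8-mers with the
classic pseudocounts: with N reference sequences of which n(w) contain
word w, and M(g) sequences of genus g of which m(w, g) contain w,

    P(w)   = (n(w) + 0.5) / (N + 1)
    P(w|g) = (m(w, g) + P(w)) / (M(g) + 1).

A read is scored per genus by Σ log P(w|g) over its distinct words (words
containing ambiguous bases are skipped; words absent from the whole
reference use the pseudocount floor P(w) = 0.5/(N+1)). The best genus wins;
exact ties go to the lexicographically smallest genus and set a tie flag.
Reads shorter than the word size are reported unclassified with that
reason.

Confidence is a bootstrap over words: 100 draws of ⌈V/8⌉ words with
replacement (V = distinct word count), each re-scored; the confidence of a
rank label is the fraction of draws whose winning genus maps to that label.
Ranks below the first rank with confidence under the threshold (default
0.8) are reported unclassified. Word size, subsample fraction, bootstrap
count and threshold are all configurable; the defaults are the published
constants of the classic RDP-style classifier. Reads are classified on the
given strand only — primer matching during QC fixes orientation.

Per-read bootstrap random streams are derived from the batch seed and the
read's position, so results do not depend on batch composition and any
subset can be reproduced in isolation. Tests verify the winner against a
brute-force argmax over exhaustively computed joint probabilities on small
instances.

## Abundance tables and diversity

Features are rank-qualified taxa (`genus:Genus_03`, `phylum:Phylum_00`) so
several ranks coexist in one table; by default all ranks phylum…genus are
used simultaneously and all features go to the classifier (no feature
selection). Reads unclassified at a rank are binned as
`unclassified_<parent>` where the parent is the finest coarser label, so
each rank block partitions a sample's reads and block column sums equal
the sample read count. Zero-total features are dropped (logged);
zero-depth samples are retained in tables, flagged, and excluded from
statistics unless forced.

Relative abundance divides each count by its sample's rank-block total —
idempotent and invariant under uniform count rescaling. Shannon diversity
is H = −Σ p_i ln p_i over positive-frequency taxa (natural log by default,
base configurable), computed at genus rank by default and optionally
appended as one extra feature (useful for medication analyses, where
overall diversity can outperform any single taxon). Appending diversity is
done after normalization; the diversity row carries H itself, not a
frequency.

## Association statistics

Per-taxon tests run on relative frequencies, not counts. The Kruskal-Wallis
test (mid-ranks, tie correction, chi-square p with levels − 1 df) covers
two or more phenotype levels; disease-activity gradings are tested across
all levels simultaneously. All-identical values return H = 0, p = 1 by
convention, and constant features are flagged rather than tested. The
two-group Wilcoxon rank-sum test uses exact enumeration when the pooled
sample is ≤ 12 without ties, otherwise the normal approximation with tie
and continuity correction; without the continuity correction the two-group
Kruskal-Wallis p agrees with it to numerical precision (tested).

Multiplicity across taxa uses Storey q-values:

    pi0(λ) = #{p > λ} / (m (1 − λ)),  λ ∈ {0.05, …, 0.95}
    q_(i)  = min_{j ≥ i} pi0 · m · p_(j) / j   (over sorted p-values).

The pi0(λ) curve is smoothed with a least-squares cubic polynomial,
weighted by sqrt(1 − λ) because the raw estimate's variance grows like
1/(m(1 − λ)), and read off at λ = 0.95, clamped to (0, 1]. With fewer than
100 p-values the tail estimate is too unstable; a warning is issued and
pi0 = 1 is used, which makes the procedure exactly Benjamini-Hochberg
(tested as an identity). Diagnostic tables (q vs p, significant count vs
cutoff, expected false positives) are available for plotting.

Effect sizes for two-level labels are Cohen's d — the pooled-SD
standardized mean difference, positive when enriched in the case class;
a zero pooled SD yields 0 for equal means and signed infinity otherwise.
Cliff's delta (a rank-based alternative bounded in [−1, 1]) is available
where the heavy tails of abundance data make d hard to interpret.

## Classification and evaluation

The classifier is a random forest (500 trees, √(#features) candidate
features per split, no class weighting; all configurable, and the learner
is pluggable behind a registry). A sample's score is the fraction of trees
voting for the positive class, giving a continuous ROC.

Evaluation is repeated stratified k-fold cross-validation (default 3
repeats of 10-fold): each repeat shuffles with its own stream derived from
the master seed, trains on k−1 folds and scores the held-out fold; the AUC
is computed from the pooled out-of-fold scores of a repeat and the
reported AUC is the median over repeats. Folds are stratified by class
because unstratified 10% holdouts can lose an entire class at realistic
cohort sizes (e.g. 24 controls); a strict-unstratified switch exists.
One-vs-rest wrappers produce one ROC per class for multi-class questions
(CD vs UC vs control).

The ROC sweep treats each distinct score as a threshold; AUC is computed by
the Mann-Whitney rank formula, so a tied positive/negative pair counts one
half and AUC ≡ U/(n₊·n₋) exactly — verified against brute-force pair
counting over random tied instances. Operating points pick the smallest
sensitivity ≥ target (ties broken toward higher specificity); confusion
matrices predict positive at score ≥ threshold.

Feature importance is permutation importance — the mean decrease in
held-out accuracy when one feature column is shuffled — measured on a
stratified 30% holdout with 5 permutation repeats. Duplicated features
split their importance (documented, tested qualitatively).

Cross-study transfer trains once on the full training cohort and scores a
second cohort on the intersection of rank-qualified feature names; features
missing from the test cohort are zero-filled with a warning, and an empty
intersection is an error listing both name sets. The default retrains on
the training cohort (blind-validation style) rather than reusing a frozen
model object; both are supported.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate (counts- or reads-mode) → normalize →
association → cross-validation from one nested config, writing TSV/JSON
outputs, a human-readable summary and a manifest with the master seed,
versions and SHA-256 digests of every output. Identical config + seed
reproduces outputs byte for byte. All random streams in the package derive
from explicit seeds via independent `SeedSequence` spawn keys.

Test and acceptance workloads use cohorts of 60/class × 200 taxa for
signal recovery, 30/class × 1000 taxa for null calibration (20
replicates), 5000 reads for taxonomy accuracy, and ~8 samples × 2000 reads
for the end-to-end read chain — sizes chosen so the full suite runs in a
few minutes on one CPU while keeping Monte-Carlo noise well inside the
asserted margins. The null-calibration uniformity check (KS on KW p-values)
runs at depth 20 000 with an even baseline: the invariant concerns the test
statistics, and at default depth most of 1000 power-law taxa have
near-zero counts whose discreteness dominates the KS distance.

## Known limitations

- The taxonomy classifier is k-mer naive-Bayes only; no alignment-based
  fallback, chimera-aware mode, or full-scale reference database handling
  beyond a streaming FASTA parse.
- Quality filtering uses the whole-read mean; windowed-quality variants of
  the era are not implemented (the policy field structure leaves room).
- No OTU clustering: reads are classified directly per read. No
  rarefaction or compositional (CLR-type) transforms.
- Storey pi0 estimation is unreliable below ~100 features by construction;
  the BH fallback is conservative.
- `simulate_reads` assumes every cohort taxon has reference sequences; it
  will not invent references for unknown taxa.
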