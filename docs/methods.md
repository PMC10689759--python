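# Methods

`cfsig` implements a multi-feature analysis of whole-genome methylation
sequencing (WGMS) of plasma cell-free DNA (cfDNA) for multi-cancer
detection and tissue-of-origin (TOO) prediction, together with a
synthetic cohort generator that provides ground truth for every stage.
This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic validation does and
does not establish.

## Feature models

### CpG blocks and the average methylation fraction (AMF)

The unit of methylation quantification is the CpG block: a maximal run
of CpG sites in which every pair of consecutive sites is at most
100 bp apart, containing at least 3 sites; runs spanning 1 kb or more
are divided into `ceil(span / 1000)` sub-blocks. Only the + strand C of
the palindromic CG defines a site; coordinates are 0-based half-open; a
block runs from its first C to just past its last G.

Interpretations where the rule leaves room (all surfaced as defaults):

* "within 100 bp" is read as inter-C gap ≤ 100; "smaller than 1 kb" as
  span < 1000 strictly;
* split boundaries fall between CpGs so sub-block CpG *counts* are as
  equal as possible (the rule asks only for "similar-sized" pieces);
  sub-blocks left with < 3 CpGs are merged into their left neighbor,
  and a piece still ≥ 1 kb after splitting (possible under very uneven
  spacing) is split again;
* the genomic blacklist removes whole blocks on ≥ 1 bp overlap, while
  the coverage mask (median healthy-training coverage ≤ 3×) removes
  individual CpGs before segmentation;
* sex chromosomes are excluded.

The block construction is verified against an independently written
quadratic brute-force segmenter on random inputs.

Per sample and block, `AMF = Σ C_j / Σ (C_j + T_j)` over the block's
CpGs, where C and T count methylated (cytosine) and converted
(thymine) base calls. The AMF is missing (NA) when the block's mean
per-CpG coverage is below 10×; CpGs with no record contribute zero
reads but still count in the denominator of the mean coverage — the
conservative reading of "average read coverage in the segment".

### Stable regions, markers, and the set algebra

Blocks whose AMF is < 0.3 in at least 90% of healthy training samples
are *healthy-unmethylated*; > 0.7 in at least 90%, *healthy-methylated*.
The 90% rule is applied to the non-missing values only, and blocks
observed in fewer than 80% of healthy training samples are excluded
from both sets — stability should not be declared from a handful of
samples. Both the ≥ in "at least 90%" and the NA handling are
documented interpretations.

Differential methylation uses an empirical-Bayes moderated t-statistic
on logit-transformed AMF (clamped to [0.01, 0.99]; the logit scale is
the analysis scale throughout, and "log FC > 1" is read as a ≥ 1
logit-unit mean difference). Per region the pooled two-sample variance
with d = nA + nB − 2 degrees of freedom is shrunk toward a prior
(d0, s0²) estimated by method-of-moments on the log variances; the
moderated t uses the shrunken variance and d0 + d degrees of freedom.
The implementation is checked against a scalar brute-force
recomputation and against reference values frozen from the standard R
implementation of the same model on a fixed fixture. FDR control is
Benjamini–Hochberg (checked against a literal step-up).

For each cancer class, three contrasts are run on each stable stratum
(hypermethylation on the unmethylated stratum, hypomethylation on the
methylated stratum): tumor tissue vs healthy cfDNA (T-H), adjacent
normal tissue vs healthy cfDNA (N-H), tumor vs normal tissue (T-N).
Selected markers pass logFC > 1 and FDR < 0.01 and are ranked by
p-value (ties: |logFC| descending, then region id) and truncated to
the top 10,000 — p-value ranking is a documented choice; the rule
names only "top". Then

* tissue-specific = (T-H ∩ N-H) \ T-N — shared by tumor and its organ;
* cancer-specific = (T-H ∩ T-N) \ N-H — malignancy-restricted;
* detection marker set = all healthy-unmethylated blocks;
* TOO marker set = detection set ∪ tissue-specific markers from the
  healthy-methylated stratum.

Externally supplied tumor-vs-normal marker lists can be unioned into
T-N before the algebra. A class without its own adjacent normal tissue
(prostate, typically) is contrasted against the pooled composite of
the other classes' normals; its tissue-specific markers are then not
discoverable — a structural property of the design, not a bug.

### Copy-number ratios (CNR)

Fragments are counted into non-overlapping bins (default 100 kb;
midpoint assignment, so each fragment lands in exactly one bin). GC
bias is corrected by median scaling within 1%-wide GC strata (adjacent
strata merged until each holds ≥ 20 bins), and corrected counts are
divided by the autosomal median, so the linear ratio has autosomal
median exactly 1. The classifier input is the *adjusted* CNR: counted
from fragments shorter than 150 bp (enriching tumor-derived
molecules), with linear ratios inside the closed interval [0.85, 1.05]
suppressed to exactly 1 before the log2 transform. The closed-interval
reading of "between 0.85 and 1.05", and applying suppression to the
corrected/normalized ratio, are documented decisions. Mappability
correction is accepted in the interface but not applied — synthetic
references are uniformly mappable — and segmentation is out of scope:
the classifier consumes per-bin adjusted CNRs, not segments.

Frequent-gain regions per class come from the same moderated-t engine
on tissue log2 CNR profiles: logFC > 0.2 / FDR < 0.01 for colon and
liver, logFC > 0.15 / FDR < 0.001 for lung and prostate, prostate vs
pooled normals. The gain contrasts run on *unsuppressed* ratios:
suppressing near-neutral normals to exactly 1 would zero their
variance and let the shrinkage prior manufacture spurious gains.

### Fragment-size ratios (FSR)

Short fragments are 80–150 bp, long fragments 151–220 bp, inclusive on
all boundaries; everything else is excluded. Per bin, the raw S/L
count ratio is divided by the chromosome-level S/L ratio and
log2-transformed. Bins with fewer than 50 short+long fragments are NA
(at WGS depth this mainly affects masked or degenerate bins; compact
demo configurations with ~50 fragments per bin lower the cutoff in
their config). NA feature bins are later imputed with healthy-training
means, symmetric with the methylation imputation rule. The per-sample
global S/L ratio uses genome totals. The healthy reference profile is
the bin-wise median over healthy samples (NA when more than half the
samples are NA), and sample-vs-reference similarity is Pearson
correlation over jointly observed bins (≥ 10 required).

## Classification

Missing feature values are imputed by the mean of the healthy training
controls with observed values; markers missing in more than 10% of
healthy training controls are discarded.

Each feature family feeds a linear-kernel support-vector classifier
over the five classes (healthy, colon, liver, lung, prostate), with
features z-scored on training statistics (required for regularized
linear models across heterogeneous scales). The regularization
constant is selected from {0.01, 0.1, 1, 10} by stratified internal CV
on misclassification (ties prefer the smaller C); probabilities are
one-vs-rest sigmoid calibrations fit on out-of-fold decision values.
The calibration mechanism is a documented choice — the ensemble
results on synthetic data are not sensitive to it.

Derived scores:

* cancer score = sum of the four cancer-class probabilities
  (= 1 − p_healthy);
* TOO conditional probabilities = cancer-class probabilities divided
  by the cancer score (uniform with a degenerate flag when the cancer
  score is ~0);
* cancer signature ensemble (CSE) = arithmetic mean of the three
  feature classifiers' cancer scores (detection) or TOO conditional
  vectors (TOO; the mean of unit-sum vectors is unit-sum).

The detection threshold is chosen post hoc on the held-out healthy
evaluation scores: the lowest candidate (unique observed score) t such
that strictly more than 95% of healthy scores are ≤ t, with calls made
by score > t. Both inequalities are strict; with 20 distinct healthy
scores no candidate qualifies (19/20 = 95% is not > 95%) and the
maximum score is returned with a warning. TOO prediction is performed
only for samples the ensemble detects, by argmax conditional
probability (ties broken in canonical class order).

Cohort handling: cfDNA samples with matched tissue are forced into the
training split; the rest are assigned by seeded sampling within
(class × stage × sex × age-bin) strata, age binned at 50. Training
folds are class-stratified (the 4-fold rule names only "4-fold").

## Evaluation

QC exclusion (strict inequalities; values exactly at a threshold
pass): < 150 million uniquely mapped reads, mapping rate < 80%,
duplication rate > 25%, conversion efficiency < 99%.
Sensitivity/specificity/accuracy carry exact Clopper–Pearson 95% CIs
(conservative and standard; the upstream CI method is unstated). AUC
is the Mann–Whitney statistic with tie correction; its CI uses the
DeLong variance (verified against a frozen reference from the standard
R implementation). McNemar's comparison of paired sensitivities uses
the exact two-sided binomial when the discordant count b + c ≤ 25 and
the continuity-corrected chi-square otherwise (the switch point is a
documented choice).

## The synthetic cohort generator

The generator defines the study conditions; its defaults are fixed and
are not tuned per experiment.

* **Reference**: random background sequence scrubbed of CG
  dinucleotides, with CpG clusters (3–12 CpGs, 4–60 bp spacing)
  planted at a configurable rate, so the planted clusters are exactly
  the CpG sites. Written as FASTA; truth equals a fresh scan by
  construction.
* **Methylation**: healthy block AMF is bimodal on the logit scale
  (modes ±3.5, sd 0.5, plus 16% intermediate mass) — the
  stably-unmethylated / stably-methylated structure of healthy plasma.
  Per cancer class, planted hyper markers (in healthy-low blocks) and
  hypo markers (in healthy-high blocks) shift the logit by the effect
  size (default 3 logit units — e.g. AMF 0.03 → ≥ 0.37 — the scale of
  strong cancer markers) plus a small uniform jitter; tissue-specific
  markers shift the class's normal-tissue archetype too,
  cancer-specific markers only the tumor. Planted sets are disjoint
  across classes and categories.
* **Counts**: per-CpG coverage is negative-binomial (size 10) with
  mean `depth × (1 + f(c/2 − 1))`, c being the local tumor copy
  number; methylated counts are beta-binomial with mean
  `(1−f)·AMF_healthy + f·AMF_tumor` and intraclass correlation 0.02 —
  realistic overdispersion that still allows desk-scale recovery.
* **Fragments**: lengths follow a three-component normal mixture. The
  healthy model has a sub-nucleosomal component at 120 bp (sd 15), the
  mononucleosome mode at 167 bp (sd 10), and a dinucleosome mode at
  334 bp (sd 25), with weights (0.108, 0.742, 0.150) calibrated so a
  healthy cohort's median global S/L ratio is ~0.2; the tumor model
  shifts the mononucleosome mode to 145 bp and doubles the
  sub-nucleosomal weight. Bin placement is proportional to bin width ×
  copy ratio × an optional logistic GC-bias factor. Healthy-origin
  fragments additionally follow a fixed per-bin lognormal modulation
  (amplitude 0.4, unit mean, constant seed) of their short-component
  weight: the shared regional fragmentation profile of healthy plasma
  that tumor-derived fragments do not follow, which is what makes a
  cancer sample's regional FSR profile decorrelate from the healthy
  median as tumor fraction grows.
* **Cohorts**: cancer cfDNA tumor fractions are drawn per stage from
  bands centered at 0.01 / 0.03 / 0.10 / 0.30 for stages 1–4 (uniform
  within [0.5×, 1.5×] of the center). No per-stage circulating-tumor
  fractions are established quantities; this mapping is a documented,
  overridable default and not an inference target. Tumor tissue mixes
  the class's normal archetype with its tumor archetype at
  f ~ U(0.4, 0.7) (tumor purity); normal tissue is the pure normal
  archetype with tumor fraction 0. Prostate normals are omitted by
  default, mirroring typical cohort availability.

Everything is deterministic: identical seeds give byte-identical
files; a single pipeline seed fans out to stage seeds through a hash.

### What the synthetic validation does and does not show

Passing tests establish that the implementation is faithful to its
stated rules: the feature mathematics are exact, marker selection
recovers planted truth under realistic noise, the post-hoc threshold
delivers its specificity guarantee by construction, and the ensemble
does not underperform its best member when signals are complementary.
They do not establish clinical performance: the generator has no
sequence-context effects, no batch or age structure, no correlated
methylation beyond the block level, uniform mappability, and
mixture-model fragment lengths without oscillatory fine structure, and
its marker effect sizes are planted rather than discovered biology.
Absolute sensitivities/AUCs on synthetic cohorts depend mainly on the
assumed stage-to-tumor-fraction mapping and should not be read as
predictions for real cohorts.

## Problem sizes used in the shipped runs

Chosen as the smallest scales at which all stochastic checks are
stable: the quick configuration uses a 2 × 2 Mb genome, ~120 samples
and 30k fragments per sample; the demonstration configuration a
4 × 5 Mb genome (~20,000 blocks, 2,000 bins of 10 kb), ~200 samples
and 100k fragments per sample; the acceptance script a 2 × 2.5 Mb
genome with 220 healthy + 224 cancer cfDNA samples (yielding > 100
healthy and > 100 cancer test samples after the stratified split) and
100k fragments per sample, plus a 50-sample healthy cohort for the
fragment-model calibration. Compact configurations scale the
FSR low-count cutoff with their per-bin fragment counts.

## Known limitations

* The moderated-t prior fit excludes zero-variance regions; with fewer
  than two usable regions it falls back to the ordinary t with a
  warning.
* Short-fragment CNR profiles at demo scale are shot-noise limited
  (tens of short fragments per bin); the copy-neutral suppression then
  mostly encodes which bins escape the interval by noise. This mirrors
  the small-data regime, not WGS depth.
* `select_threshold` guarantees its specificity only on the score set
  it was given; generalization to new healthy cohorts is a statistical
  question the package reports CIs for, not a guarantee.
* The CLI and workflow target the synthetic cohorts; real data can
  enter at any stage boundary (count tables, fragment BED, matrices)
  but alignment and methylation calling are out of scope.
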