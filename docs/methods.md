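# Methods

## Setting and data model

The package analyzes longitudinal targeted-panel sequencing of cell-free
DNA. The unit of observation is one variant in one sample: alternate and
total read counts at a locus, from which the variant allele frequency
(VAF) is always recomputed (input VAF columns are ignored — counts are
the ground truth the exact tests condition on). Coordinates are 1-based
and fully closed throughout, matching VCF; multi-allelic records are
decomposed into one observation per alternate allele with depth equal to
the sum of allelic depths. Inputs are assumed left-normalized upstream;
no indel realignment is attempted.

Samples carry a material (plasma, tissue, germline), a timepoint in days
from the start of chemotherapy, and a treatment phase. Exactly one
germline blood control per patient is required for somatic filtering.
Responder truth labels derive from the platinum-free interval: poor iff
PFI <= 12 months (covering platinum-resistant, < 6, and partially
sensitive, 6–12), good iff PFI > 12.

## Somatic filter chain

Four rules, applied as germline -> detection -> CADD -> cross-patient
artifact; the first three are per-variant independent predicates, so
their order cannot change the kept set (asserted by a permutation test).
All thresholds are inclusive on the keep side.

- **Germline**: pass iff germline alt reads <= 2 **or** germline VAF
  <= 0.001. A variant absent from the germline sample counts as 0 reads.
- **Detection**: pass iff max VAF over the patient's plasma and tissue
  samples >= 1%.
- **CADD**: fail iff a score is present and < 15. Missing scores pass
  with a recorded flag because indels are frequently unscored; a strict
  mode inverts this.
- **Cross-patient artifact**: after the per-patient rules, an identical
  (chrom, pos, ref, alt) key kept in >= 2 distinct patients and not on
  the whitelist is removed from every patient. The whitelist defaults to
  {TP53} (mutated in essentially all HGSOC, so true recurrence is
  expected) and accepts user-supplied hotspot keys. Exact-key recurrence
  is deliberately conservative; no positional window clustering is
  attempted, since recurrent artifacts from library or alignment error
  reproduce at identical keys.

The chain emits an audit table with one row per (patient, variant, rule)
so every removal is attributable.

## Decrease testing and the responder statistic

For pretreatment counts (a₁, d₁) and on-treatment counts (a₂, d₂) the
decrease p-value is the one-sided Fisher exact test on
[[a₁, d₁−a₁], [a₂, d₂−a₂]] with alternative "later VAF smaller", i.e.
the upper hypergeometric tail P(X >= a₁) with population d₁+d₂, draws d₁,
successes a₁+a₂. Zero depth on either side is undefined and excluded
from proportions. The reference is always the earliest pretreatment
*plasma* sample — never tissue, which differs systematically in tumor
content and would confound plasma-to-plasma kinetics.

Per patient and per on/post-treatment plasma sample s,
d(s) = k(s)/n(s) with k the number of variants with p < alpha
(default 0.01) and n the evaluable variants. The responder statistic is
max_s d(s), reported raw and **count-corrected** as the 95% Jeffreys
lower bound of the maximizing k/n: the 2.5% quantile of
Beta(k+½, n−k+½), with the conventional 0 at k = 0. The correction
penalizes proportions computed from few variants (1/1 corrects to 0.09;
8/8 to 0.68), keeping corrected <= raw everywhere. The published form of
the original count correction is not available, so this explicit,
testable choice is documented as the package's own; the raw value is
always reported beside it.

Classification: good iff n_mutations <= 10 **or** corrected >= 0.5, else
poor; both cutoffs are configuration. This encodes the observed pattern
that good responders show either few mutations or a large decreasing
fraction. Group differences are tested with a one-sided Mann–Whitney U
(exact for pooled n <= 20 without ties, midrank-corrected asymptotic
otherwise; identical pooled values return 0.5). The choice of test is a
package decision — small cohorts demand an exact rank test.

## Tumor burden

Burden per plasma sample is tracked by the truncal TP53 variant — the
tracked TP53 variant with maximal VAF in the earliest pretreatment tissue
(fallback: pretreatment plasma; ties by genomic position) — alongside the
median VAF over tracked variants. Three ctDNA-fraction models transform
the TP53 VAF V: `direct` f = V (the default: the VAF itself is the
conventional burden proxy), `het` f = min(1, 2V) (heterozygous variant,
diploid locus), `loh` f = 2V/(1+V) (wild-type allele lost). All are
monotone, so model choice never reorders samples.

Trajectories are completed: every tracked variant gets a point at every
plasma sample, with absent records imputed as 0 alt reads at the sample's
median observed depth (the configured panel depth when nothing was
observed); imputed points are flagged.

## Copy-number calling

Per-target depths are divided by the sample's median target depth; a
gene's relative coverage is the median over its targets; >= 3 normal
samples define a per-gene reference median and MAD. The gene log2 ratio
is log2(sample_rel / normals_median), with a percentile bootstrap
(default 1000 resamples) over the gene's targets for a 95% interval and a
robust z against the normals. Calls: amp iff the interval lies above 0
and log2 >= 0.58 (3 copies at purity 1); del iff below 0 and
log2 <= −0.41 (1.5 copies); neutral otherwise. Genes with < 3 targets
are flagged low-confidence. Bootstrap streams derive deterministically
from (seed, sample, gene) via CRC32-keyed seed sequences, so calls are
reproducible per gene regardless of batch composition. No GC or
mappability correction is applied — the synthetic panel has no GC bias —
but the per-target normalization table is the hook where one would go.

Under tumor fraction f the expected ratio of a c-copy gene is
log2((f·c + 2(1−f))/2), strictly increasing in c and 0 at c = 2; its
inverse provides purity-adjusted copy estimates. CNA concordance between
materials is restricted to plasma samples with ctDNA fraction > 0.30
(below that, panel-level copy signal drowns in normal cfDNA) and counts
direction-agreeing non-neutral calls over non-neutral tissue calls.

## Actionability

The knowledgebase is a flat TSV of (gene, alteration class, optional
exact variant pattern, drug, sensitivity/resistance, ESCAT tier).
ESCAT is a closed total order I-A ... X; unknown tiers are rejected at
load with row numbers. Mutations match mutation-class entries by gene
(the caller cannot distinguish gain from loss of function, so all
mutation classes are eligible unless a variant pattern restricts the
match); CNA calls match amplification/deletion entries by direction;
germline-deletion entries additionally require an explicit germline flag
on the input. Findings are ranked by tier then supporting VAF. "High
confidence" means the alteration passed all somatic filters and, for
CNAs, carries a bootstrap-supported non-neutral call. The bundled
knowledgebase is a small illustrative fixture of well-known HGSOC
associations; its tier assignments are indicative, and real use requires
a curated knowledgebase.

## Over-representation

Genes qualify when >= 1 tracked variant has an evaluable decrease
p >= alpha at the patient's *last* on/post-treatment sample (configurable
to all samples) for >= 1 patient in scope — the persistently mutated
genes. The test is the upper hypergeometric tail of the overlap with
each gene set, conditioned on the panel gene list as background (the
genome would be the wrong conditioning for panel data: selection can only
ever see panel genes). The battery is Benjamini–Hochberg adjusted.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 12
patients (6 good / 6 poor responders), one germline control and one
pretreatment tissue at 200x, six plasma timepoints at 1000x (days −7,
21, 63, 126, 250, 360 against 21-day chemotherapy cycles), a ~500-gene
panel.

Each patient has a truncal TP53 clone (cellular fraction 1) and
subclones; a variant's expected VAF is 0.5 · f_material · CF ·
decay^cycles (heterozygous dosage). Good responders' clones decay at
0.1/cycle. Poor responders are a mixture: the truncal clone and 40% of
subclones decay at 0.8/cycle while 60% of subclones persist (multiplier
1.0) — the resistant populations whose expansion defines chemoresistance
— and the truncal clone rebounds to a 0.8 factor at the progression
sample. A uniform 0.8/cycle decay for poor responders would, at 1000x
depth, make nearly every poor-responder variant a significant Fisher
decrease by treatment end and erase the very contrast the responder
statistic measures; the persistent mixture is what "stable or increasing
mutation frequency in poor responders" means operationally. Pretreatment
plasma fractions draw from U(0.2, 0.35), tissue from U(0.3, 0.7);
subclone cellular fractions from U(0.12, 0.9) (good) and U(0.05, 0.6)
(poor, reflecting greater subclonal diversity); mutation counts 6–12
(good) and 18–40 (poor). Poor responders carry persistent
chromatin-regulator clones (KMT2A/B/D, KDM5A, SUZ12, SMARCD1, SMARCA4)
and seven patients carry planted actionable alterations (four mutations,
three amplifications), mirroring the cohort composition the workflow is
designed for.

Observed alt counts are Binomial(depth, VAF). Germline controls draw
Binomial(depth, 3·10⁻⁴) at somatic sites — a contamination rate at which
the <= 2-read germline rule passes a true somatic at 200x with
probability > 0.98 (Binomial CDF check in the tests). Cross-patient
artifacts are planted at identical keys in four patients with expected
VAF ~ U(0.005, 0.02) and high CADD, so only the artifact rule removes
them. Per-gene target depths (5–12 targets per gene) are negative
binomial with size 200 (per-target CV ≈ 7%, typical of hybrid-capture
panels) and mean scaled by (f·c + 2(1−f))/2 per the planted copy states.
CA-125 is log-linear in tumor fraction with lognormal noise.

Crucially, the cohort *structure* — patients, clones, cellular
fractions, artifact keys, copy events, responder labels — comes from a
fixed internal layout; the sampling seed redraws only read counts, CA-125
noise and coverage. Truth tables are therefore identical across seeds,
and seed-swept recovery metrics are well defined.

What the generator does **not** model: sequencing error spectra beyond
flat contamination, GC/mappability coverage bias, clonal hematopoiesis,
subclonal copy number, overlapping variant phasing, and sample-to-sample
depth variation beyond the negative binomial. Passing recovery tests
therefore demonstrate internal consistency of the statistical machinery
under the stated model, not robustness to every artifact of real panels.

## Evaluation sizes and numerical choices

The exact-test oracle sweep enumerates all 2x2 tables with both depths
<= 30 (245,025 tables) against binomial-coefficient tail sums. The
recovery sweep uses 100 seeds of the default 12-patient cohort
(coverage simulation off there, as none of the scored quantities touch
it), scoring tumor-fraction MAE at true fraction >= 0.05 with the
heterozygous model — matched to the generator's dosage — and responder
label recovery. CNA calibration uses one pretreatment plasma sample
against the twelve germline normals (~498 null genes) and a 100-seed
planted 8-copy amplification at fraction 0.2 on an eight-target gene.
Ties everywhere break deterministically: genomic order, then allele,
then sample id; the maximizing sample for the decrease statistic breaks
toward the earliest timepoint.

Known limitations: the mutation-count correction and the responder
cutoffs are principled stand-ins, configurable and reported alongside raw
values; the artifact filter's exact-key matching will miss artifacts
that shift alignment between samples; copy-number calling is gene-level
only (no segmentation, no allele-specific states); and the bundled
knowledgebase is illustrative, not clinical.
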