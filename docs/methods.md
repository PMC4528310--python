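# Methods

## The consolidation cascade

The pipeline treats "somatic variant" as a decision, not an observation:
a candidate exists wherever any of seven callers emitted a call, and it is
retained only if it survives eight rules evaluated on the calls grouped by
normalized variant key.  Normalization (right-trim of shared suffix,
left-extension against the reference, prefix strip down to the indel anchor
base) makes matching representation-independent: two callers spelling the
same deletion differently collapse to one candidate.  The matching-by-
normalized-key choice is this package's; consensus callers in the wild vary
between exact-representation and position-only matching, and normalized
exact-allele matching is the reproducible middle ground.

Rule semantics where a per-call rule must become a per-variant verdict:

* **evidence** (≥10 tumor reads for Pindel, ≥2 otherwise) is satisfied if
  *any* call meets its own caller's threshold — the most permissive reading
  of "the variant was present in ≥N reads", and configurable.
* **germline fraction ≤5 %** is evaluated on the *maximum* germline VAF
  across callers reporting the variant — conservative against germline
  leakage.  Calls with zero germline depth contribute 0 % but mark the
  decision low-confidence rather than rejecting it (no depth floor is part
  of the cascade).
* **tumor–germline gap ≥10 points** applies only to indels reported by the
  tumor/germline-separate callers (Pindel, Unified Genotyper), because the
  jointly-genotyping somatic callers already condition on the matched
  germline.  A variant with such calls passes if any one of them shows the
  gap; an indel also supported by a joint somatic caller still must show
  the gap on its separate-caller calls, which keeps the rule a genuine
  screen on the leak-prone call source.
* The **coding/splice restriction** runs last so that the audit trail
  separates biological-context rejections from evidence rejections.
  `failed_rules` records *every* failed rule, while the report's funnel
  attributes each rejected variant to its first failure, so funnel counts
  are conserved (candidates = retained + Σ first-failures).

Splice sites are the two intronic bases flanking each internal exon
boundary; exonic junction bases are classified by their codon effect.
Indels that straddle a CDS/intron boundary are classified `splice_site`
(the conservative call); stop-loss and start-loss substitutions are binned
as missense because the reporting categories do not separate them.  Gene
models are single-transcript — isoform selection belongs to a full
annotator, not to this pipeline's logic.

Manual review of alignments (IGV-style) is deliberately not emulated:
it is not an algorithm, and adding a stand-in heuristic would change the
cascade's measurable behavior in unspecifiable ways.

## Spectrum and burden conventions

Substitutions are collapsed to pyrimidine-reference classes, so G>A counts
as C>T; trinucleotide contexts are reported with the mutated pyrimidine
central, reverse-complementing when the reference base is a purine.
"NpCpG" means the oriented central C is followed by a 3′ G — the
5-methylcytosine deamination motif — with any 5′ base.  SNVs at contig
edges or with N in the 3-mer are excluded from context counts but kept in
the six-class totals, so the two tallies reconcile explicitly
(Σ contexts + excluded = Σ six-class = n substitutions).

Burden is coding mutations per megabase of callable territory; a sample
above 10/Mb is flagged as a hypermutator.  Group rates are pooled (total
mutations / total territory), not means of per-sample rates, because
callable territory legitimately differs between samples (different capture
designs between discovery and validation cohorts); per-gene recurrence
denominators differ for the same reason.

Percentages destined for tables are rounded half-up at one decimal using
exact rational arithmetic, matching clinical-table conventions and avoiding
binary-float artifacts.

## Statistics

Fisher's exact test (2×2) is two-sided by probability-mass ordering: the
p-value sums hypergeometric probabilities, over all tables with the
observed margins, not exceeding the observed table's probability.  This is
the scipy/R convention; published two-sided values computed by doubling the
smaller tail can differ by up to a factor ~2 near the null boundary.  The
chi-square test is uncorrected Pearson by default with an optional Yates
flag (2×2).  Burden comparisons use the two-sided Mann–Whitney U test —
an explicit choice for small, skewed per-group burden distributions —
exact for ≤8 observations per group without ties, normal approximation
with tie correction otherwise.

## The synthetic cohort

The generator is the package's substitute for protected patient data; its
defaults are chosen once to emulate the study conditions of a three-group
ovarian-tumor exome cohort and are not tuning knobs.

**Scaled-down geometry, full-scale statistics.**  Physical sequence is a
mini-exome: 2 contigs × 400 kb at GC 0.45, tiled with 220 single-transcript
genes (4 × 150 bp exons, 200 bp introns), ~132 kb of CDS.  Each pair
additionally carries a *nominal* callable territory per histology group —
31.75 / 36.5 / 44.6 Mb for benign / borderline / carcinoma, derived from
the published per-group mean counts and rates (25.4 @ 0.8, 32.9 @ 0.9,
66.9 @ 1.5 mutations/Mb) — and the somatic count per pair is Poisson with
mean rate × nominal territory.  Mutation *counts per sample* and
*burdens per Mb* therefore match full-exome study conditions while
coordinates stay on small contigs.  The cohort is 5 benign + 8 borderline
+ 11 carcinoma pairs, the discovery-cohort composition.

**Signature.**  Somatic SNVs are drawn from a joint (site, substitution)
weight model over CDS positions: transitions carry weight 2 relative to
transversions, and C>T at CpG cytosines is additionally boosted by
`cpg_ct_weight` (default 8).  With weight 1 the model reduces to uniform
sites with transition bias, and the C>T@CpG share equals the genome's CpG
opportunity fraction — the property the tests exploit.  With the default
weight the cohort spectrum is C>T-dominated (~41 %) with ~72 % of C>T in
NpCpG, reproducing the qualitative deamination pattern; exact published
fractions are cohort properties of real data and are not simulation
targets.  8.4 % of somatic events are indels (1–6 bp, insertions and
deletions equally likely).

**Germline model.**  A population catalog of polymorphic sites (MAF ~
U(0.01, 0.5), 5 % indels) is sized so each individual carries ~5×10⁻⁴
heterozygous variants per bp; genotypes are drawn per pair from
Hardy-Weinberg carrier probabilities, which makes common variants shared
across the cohort (so the ≤2-other-germlines panel rule has real hits).
External panel counts are Binomial(147, carrier probability); 90 % of
catalog sites appear in the population-frequency table, the rest are
"novel" — so the population rule binds on common known variants only.

**Read model.**  Depths are negative binomial (mean 144, dispersion 26,
giving the ~50–220× range); tumor alt reads are Binomial(depth, VAF) with
somatic VAF ~ Beta(mean 0.35, concentration 20); germline alt reads at
somatic sites are Binomial(depth, 0.005), so the ≤5 % germline rule passes
almost all true somatics but binds occasionally.

**Caller emulation.**  Each caller has a class scope (SNV-only,
indel-only, both), per-class sensitivity (0.80–0.97 by caller), and a
uniform genome-wide false-positive rate (3–30 per physical Mb, with FP VAFs
~ Beta(1.2, 25) so read-support thresholds bind).  The
tumor/germline-separate callers (Pindel, Unified Genotyper) additionally
report germline variants in the tumor call set — the leakage the
germline-fraction and gap rules exist to remove.  Detection events are
independent across callers, which is what makes the closed-form ≥2-of-5
consensus sensitivity 1 − Π(1−sᵢ) − Σ sᵢ Π_{j≠i}(1−s_j) testable; real
callers' errors correlate through shared alignments, so measured consensus
sensitivity on real data will be below this bound.

**What the simulation does not model** — and hence what passing tests do
not establish about real data: sequencing error and mapping artifacts
(false positives are uniform, not context-driven), correlated caller
errors, FFPE damage, tumor purity/subclonal structure beyond a single VAF
distribution, multi-transcript annotation, and copy-number effects on VAF.

**Determinism.**  Every random draw flows from one `numpy` generator
seeded by `SimConfig.seed`, in a fixed iteration order; outputs carry no
timestamps.  Two runs with the same config are byte-identical, checksummed
in `manifest.json`.

## Problem sizes used in the checks

The acceptance checks run at sizes a laptop handles in minutes: the
consensus-composition check uses one pair with Poisson-mean 1000 SNVs; the
NpCpG-recovery check compares two 6-pair cohorts (weight 8 vs 1, one-sided
Fisher at α = 0.01); the Fisher-vs-enumeration sweep is exhaustive over all
2×2 tables with N ≤ 60 (635 376 tables); end-to-end determinism uses a
6-pair cohort, and the acceptance script's pipeline metrics use the full
24-pair default.

## Known limitations

* The cascade audits but does not emulate manual alignment review, so its
  precision on real data depends on upstream BAM quality.
* Single-transcript gene models mean consequence categories can differ
  from a multi-isoform annotator (e.g., a variant synonymous in one
  transcript, missense in another).
* The external-panel rule counts genotype calls, not read-level support;
  panels built from raw read evidence would bind more often.
* Population-frequency and panel catalogs are keyed by normalized variant;
  multi-allelic population sites are represented as independent alleles.
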