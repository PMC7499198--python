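# Methods

## Gene model and coordinates

All internal intervals are 0-based half-open; GTF/GFF3 (1-based inclusive)
and VCF POS (1-based) are converted at the I/O boundary. A gene's "exonic"
territory is the union-merge of exon rows over **all** transcripts, not a
canonical transcript (the annotation formats do not force a choice and a
union is the conservative reading for impact classification; a
canonical-only mode can be built by filtering the input annotation to one
transcript per gene). Introns are derived as the complement of the exon
union within the gene span, so exons and introns exactly tile the span —
an invariant the test suite asserts. Strand is carried but plays no role
in classification. Gene biotype is not filtered: non-coding genes
(lincRNAs, miRNAs) are legitimate SV-genes and must stay in.

For symbolic DEL/DUP/INV records the variant span is taken as
`[POS-1, POS-1+|SVLEN|)`; when SVLEN is absent the span ends at INFO/END.
This matches callsets in which the printed interval length equals |SVLEN|
and sidesteps htslib's record-length heuristics when both fields are
present. Insertions occupy the single anchor base `[POS-1, POS)`.
Breakends are one record per side, paired by MATEID or by the ALT
bracket coordinates; a breakend with no resolvable mate is kept and
flagged unpaired rather than dropped.

## Region classification

The classifier evaluates an SV per overlapped gene using its two
breakpoints (first and last affected base):

- both breakpoints inside exons → **exonic**; if the span additionally
  crosses an exon boundary (e.g. exon → intron → exon), the gene is
  *also* **splicing** — both labels are reported;
- any exon edge strictly inside the span otherwise → **splicing**;
- both breakpoints inside the gene with no exon edge crossed →
  **intronic** (the SV sits inside one intron);
- an SV that overlaps no gene at all → a single **intergenic**
  assignment to the nearest gene, with the distance in bp.

An SV that contains an entire gene (both breakpoints outside it) crosses
that gene's exon boundaries and is therefore splicing for it. Breakends
are classified from the breakend base alone (exonic / intronic /
intergenic), since a translocation has no meaningful interval span.
Intergenic SVs anchor the nearest-gene query at the interval midpoint
(breakend base for BND); nearest-gene ties are broken by lower span
start, then lexicographic gene id. SVs overlapping several genes yield
one assignment per gene with no severity pruning.

Quality filters precede classification: PASS filter status and length
≥ 50 bp. Breakends carry no meaningful SVLEN and are exempt from the
length rule — dropping all translocations would be wrong for a class that
demonstrably produces exonic hits — and this exemption is a documented
choice, not a convention of the callers.

## Recurrent loci

Calls are merged across samples into loci by single-linkage clustering of
same-type, same-chromosome SVs whose breakpoints agree within ±50 bp and
(for interval types) whose reciprocal overlap is ≥ 0.8. Both defaults are
exposed (`merge_window`, `reciprocal_overlap`); there is no community
standard for SV identity across samples, and these values are deliberately
strict so that a reported "recurrent" locus means near-identical
breakpoints. Clustering is input-order invariant and deterministic
(clusters sorted by coordinate, ids assigned after sorting). The rare
recurrent filter keeps clusters with ≥ 2 case carriers and either zero
control carriers (case-only mode) or control carrier frequency < 0.5%.

## Association model

The unit of testing is the carrier indicator: a sample either carries
≥ 1 qualifying SV for a key (gene, region class, SV type) or it does not;
multiple events never count twice. Per stratum, each observed key gets the
carrier 2×2 table, the cross-product odds ratio (Haldane +0.5 on all
cells only when some cell is zero; none of the printed reference tables
need it), a Woolf log-OR 95% interval, the Pearson chi-square test and
the two-sided Fisher exact test. The chi-square default is **without**
Yates correction, with a flag to enable it: recomputing the published
p-values from their printed counts matches neither convention exactly
(per-key denominators likely differed due to missingness in the original
data), so the package documents both and anchors its tests on the odds
ratios, which do reproduce. Degenerate tables (a zero margin) report
statistic 0 and p = 1 rather than erroring.

Bonferroni correction multiplies by the family size, capped at 1; the
family is the set of tests within one (stratum × region class) by
default, with a `per_stratum` mode and an explicit `m` override because
"the number of tested variations or genes" is genuinely ambiguous.
Significant sets are driven by the **raw** chi-square p at α (0.05
default) restricted to risk keys (OR > 1) — mirroring how such studies
report their gene lists, while the adjusted values are always emitted
alongside. Meta-analysis across strata is Fisher's combined probability
test on the per-stratum chi-square p-values, chosen because it exactly
reproduces the published two-stratum example (0.79, 0.0032 → 0.0176);
a single stratum passes through unchanged via the df = 2 closed form,
and p = 0 inputs are rejected with advice to substitute the smallest
representable value.

## Synthetic cohorts

The generator lays non-overlapping multi-exon genes across ≥ 2
chromosomes (defaults: 3–8 exons of 150–400 bp, introns 0.5–3 kb,
intergenic gaps 5–20 kb) and draws two kinds of calls:

- **planted effects** — recurrent SVs (identical coordinates across
  carriers) of a requested (gene, class, type), placed by construction
  and *validated by running the real classifier*; carrier status is
  Bernoulli with control frequency `f` and case probability
  `Rf/(1−f+Rf)` for planted carrier OR `R`, so parameter recovery is a
  closed loop;
- **background** SVs following a configurable region-class mix (defaults
  heavily non-coding: ≈ 1% exonic, 0.6% splicing, 42% intronic, 56%
  intergenic) and type mix, jittered per event, avoiding effect genes by
  default so truth stays clean.

Everything is driven by one integer seed through numpy's Generator;
outputs are byte-deterministic. Three presets define the study designs
used by the validation experiments:

- `paper_shaped_scenario`: strata AA 116/408 and EA 89/262 (205 cases,
  670 controls), 200 genes, 16 AA and 16 EA effect genes with 2 shared
  (Jaccard ≈ 0.067, echoing the low cross-ancestry overlap such studies
  report), effect ORs 2–5 at control frequencies 0.02–0.08, background
  rate 8 SVs/sample.
- `null_scenario`: 200 genes, every gene an OR = 1 intronic deletion at
  carrier frequency 0.05 in a 116/408 stratum. The frequency is set where
  expected cell counts (≈ 6 case, 20 control carriers) make the
  chi-square asymptotics valid, so the experiment measures calibration of
  the test rather than small-count breakdown.
- `recovery_scenario`: one planted intronic deletion (f = 0.05, OR = 3)
  among a 10-gene matched null panel at 116/408. The panel size comes
  from an a-priori power analysis: the planted effect's chi-square
  noncentrality at these sizes is ≈ 10.5, and against larger null panels
  the maximum of the null statistics routinely exceeds it — at ~200 null
  genes the top-rank probability is only ≈ 0.55 no matter the background
  frequency. Against 10 nulls, with ranking restricted to risk (OR > 1)
  keys as in the downstream analysis, the planted gene ranks first in
  ≈ 90% of cohorts, which is the regime in which a rank-based recovery
  check is informative.

What the simulator does **not** emulate: realistic human SV length and
density spectra, linkage between variants, genotyping error, relatedness
or ancestry admixture within a stratum, and multi-breakend complex
events. Passing the recovery experiments therefore demonstrates the
correctness and calibration of the pipeline's arithmetic on its stated
model — not power on real WGS callsets.

## Validation experiments and problem sizes

`svburden.experiments` runs the full simulate → classify → carrier matrix
→ fit chain per cohort. The type-I experiment pools 10 null cohorts
(2 000 tests) and checks the fraction of raw chi-square p < 0.05; the
recovery experiment runs 300 cohorts (Monte-Carlo s.e. of the rank-1 rate
≈ 1.7%) and reports the median estimated OR and the rate at which the
planted gene tops the risk-ranked list. These sizes keep each experiment
under a minute while making the estimates tight relative to the
tolerances the tests assert. Statistical cross-checks use independent
oracles: exact integer hypergeometric enumeration for the Fisher test,
label-permutation (hypergeometric) sampling bracketing the chi-square
tail, and a linear-scan interval classifier for the annotation logic.

## Numerical and degenerate-input policy

- p-values are clamped to [0, 1] by construction; Bonferroni caps at 1.
- Keys with zero carriers in a stratum are not tested there (their table
  carries no information); meta-analysis combines only the strata in
  which a key was tested.
- Chi-square p-values of exactly 0 underflow is guarded before
  meta-combination by substituting the smallest positive double.
- Unknown chromosomes in queries return intergenic-with-warning by
  default; a strict mode raises instead.
- All pipeline artifacts are plain TSV/BED/JSON with a provenance header
  (stage, config hash, seed) and no timestamps, so a rerun with the same
  config is byte-identical.

## Known limitations

- The merge criterion for recurrence is a stated convention, not an
  inference from data; loci split or merged near the thresholds should be
  reviewed manually.
- Carrier-level testing ignores genotype (het/hom) and dosage; a
  copy-number-aware model is out of scope.
- The Bonferroni family definition materially changes adjusted values;
  users comparing to published adjusted columns must match the family.
- Gene-set analysis is a membership tally of significant/trend hits, not
  an enrichment statistic.
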