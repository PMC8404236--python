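# Methods

This note documents the models, parameter choices and numerical conventions
behind `ampliscreen`, and what the synthetic data can and cannot establish
about behavior on real sequencing runs.

## Panel model and fixture tables

The screened panel is 40 variants: 38 SNVs/indels genotyped from reads, one
short-tandem-repeat expansion (the *FXN* intron-1 GAA tract, handled by the
dedicated repeat caller), and one 36.8 kb multi-exon deletion (TRPM1)
represented as a region-deletion record but excluded from read-level
genotyping — CNV calling from a single amplicon is not part of the assay
model, and the deletion enters only the table statistics.

Coordinates are stored 1-based with anchored ref/alt allele strings exactly
as published (VCF convention); indels are deliberately **not** re-normalized
or left-aligned, because the printed representation is the identity under
which carrier counts were reported. Amplicon-local offsets are 0-based
half-open. Phenotype identity is exact string equality of the phenotype
column; that convention alone reproduces the published "distinct
conditions" counts (25 of 33 variants; 17 of the 20 above the screening
threshold; 13 of the 16 shared with the comparison population) without any
curation judgment.

Two frequency tables ship as verbatim TSV fixtures with recorded sha256
checksums: the 33-variant table from the small 100%-ancestry cohort (with a
comparison-population column) and the 22-variant table from the large mixed
cohorts (three population columns, "ND" where an assay was unavailable).
Loading cross-checks every printed percent against `100·k/n` and warns
beyond ±0.005. One known source inconsistency is preserved as printed: the
DSE frameshift appears with 1/369 carriers in the small cohort but 0/3401
in the mixed cohort, and the GPT2 variant's name and HGVS string disagree
(c.159 vs c.459); fixtures do not reconcile either.

## Synthetic cohorts

The generator emulates the study design, not any particular wet-lab run:

- **Genotypes.** Published *carrier* frequencies `cf` are converted to
  allele frequencies by the exact Hardy–Weinberg inversion
  `q = 1 − sqrt(1 − cf)` (the common `q ≈ cf/2` shortcut is biased for the
  panel's larger frequencies, e.g. 3.96%). Genotypes are drawn per
  individual: hom-alt with probability `q²`, het with `2q(1−q)`.
- **Families.** Each family draws a sibship size from a configurable
  distribution (default: singletons); siblings share a family id and the
  four grandparental ancestry labels (drawn i.i.d. from a configurable pool,
  default 55% Syrian / 15% Iranian / 20% Ashkenazi / 10% other). Genotypes
  are drawn independently per individual — the analysis uses family
  structure only for the one-sibling-per-family dedup rule, never for
  within-family genotype correlation.
- **Repeat alleles.** Each *FXN* allele is expanded with probability
  `1 − sqrt(1 − p)` for a configured expansion carrier probability `p`.
  Normal alleles are uniform on [8, 30] triplets and expanded alleles
  uniform on [70, 1000]. The caller's decision boundary is 35 triplets;
  these defaults keep the classes separated so that sensitivity/specificity
  tests measure the algorithm, while boundary behavior (exactly 35) is
  exercised by dedicated unit tests.
- **Reads.** Single-end 250 bp reads, uniform start positions per
  haplotype, per-amplicon depth Poisson(100) by default (split evenly
  across the two haplotypes of a het site and across the two repeat
  alleles), substitution errors at 0.3% per base. No indel errors, PCR
  stutter/duplicates, quality miscalibration, or index hopping are
  simulated: substitution-dominance matches amplicon short-read error
  profiles and keeps repeat-count arithmetic analyzable. Read length and
  depth were not published; 250 bp / 100× are declared defaults satisfying
  the structural constraint `read_length ≥ 3·36 + 2·anchor_len` (a read
  must be able to hold a >35-triplet run plus flank anchors).
- **Randomness.** One top-level seed; cohort draws and cohort-level read
  generation use streams derived from it, so a fixed config reproduces
  byte-identical outputs. Standalone per-person read simulation derives its
  stream from (seed, sample id) so output does not depend on cohort order.

Because amplicon primer coordinates are not public, each genotypable
variant receives its own synthetic 400 bp local reference with the ref
allele embedded at offset 189 (every full-length read therefore covers the
site), generated once from a fixed internal seed like a reference genome,
and screened to contain no GAA run of ≥4 triplets. Two real variants 4 bp
apart (SMPD1) would share a physical amplicon; they get separate synthetic
ones, which changes nothing downstream since genotyping is per-site. The
non-repeat flank of the repeat locus ships as a clearly labelled synthetic
400 bp sequence whose one load-bearing property — no GAA run of ≥4
triplets — is validated at construction; a real locus sequence can be
supplied instead.

**What passing tests do and do not show.** Parameter-recovery and
concordance results on this generator demonstrate the pipeline's
correctness under its own statistical assumptions (independent sites, HWE,
uniform coverage, substitution-only errors). They do not measure robustness
to PCR stutter in the GAA tract, allele dropout, coverage skew, or
population structure; on real data the repeat caller's specificity margin
(normal alleles ≤ 30 vs threshold 35) would be narrower than simulated if
stutter lengthens apparent runs.

## Genotyping

Three transparent stages, with all thresholds fixed:

1. **Assignment** — a read goes to the amplicon sharing the most k-mers
   (k = 21 in the pipeline; contract minimum k ≥ 11), requiring ≥3 shared
   k-mers and a unique winner; ties and weak matches are unassigned.
2. **Alignment** — affine-gap Gotoh dynamic programming, global in the
   read with free target end gaps: match +1, mismatch −1, gap open −3
   (first gapped base), extend −1. The DP is vectorized per read base, with
   the target-consuming gap state computed by a running maximum (valid
   because affine cost is linear in gap length). Ties take the leftmost end
   position and prefer diagonal moves in traceback. Reads scoring below
   −0.2·length are discarded. An exhaustive alignment-enumeration oracle on
   tiny cases pins the DP's optimality in tests. An earlier edlib-based
   variant was rejected: minimum-edit paths are non-unique and edlib may
   scatter a multi-base insertion into interleaved single-base ops, which
   breaks indel allele matching and the declared scoring.
3. **Pileup calling** — each aligned read covering the ref-allele interval
   is classified ref / alt / other; alt support requires the full printed
   alt allele string (insertions at the interval's internal junctions and
   right edge are included, so anchored duplications are recoverable), and
   partial indel overlaps count as "other". With informative depth
   `ref+alt < 20`: no-call; otherwise hom-ref / het / hom-alt by alt
   fraction against the inclusive band [0.20, 0.80]. These are conventional
   amplicon thresholds, declared so tests can be exact.

At cohort scale the pipeline uses a fast placement route: a k-mer-seeded
ungapped check against the ref and alt haplotypes (Hamming ≤ 6, ~7 errors
on a 250 bp read at 0.3% is a ≈1e−7 event), falling back to full assignment
and gapped alignment otherwise. Tests assert the fast and literal routes
produce identical pileups.

## Repeat-expansion calling

Reads containing a GAA-motif run are triaged to the repeat caller (any run
of ≥4 triplets contains the 10-mer `GAAGAAGAAG`, used as a cheap prefilter),
as are reads matching the repeat-locus amplicon. Classification mirrors the
intent of split-read extraction after decoy-reference mapping, directly in
sequence space:

- *split read*: GAA run ≥ 4 triplets **and** a flank anchor — ≥ 20 bases
  matching the non-repeat flank exactly or with one mismatch (one
  sequencing error tolerated; 20 bp is unique within a short amplicon);
- *pure repeat*: run without anchor (interior reads of long expansions);
- *non-repeat*: everything else (contributes nothing).

Both split and pure-repeat reads contribute a repeat count — the longest
tandem GAA run in triplets over all three phase rotations — because
interior reads of a long expansion carry the strongest evidence and the
decision rule is insensitive to the choice at realistic depths. Per sample,
counts are sorted descending; the top three form the final report, and the
sample is a carrier iff at least two strictly exceed the 35-triplet
threshold. The rule is monotone in the threshold and read-order invariant
(both property-tested). With 250 bp reads the largest observable count is
83 triplets, so the statistic saturates far above the threshold — the
caller detects carrier state, not expansion length.

## Cohort statistics

- **Eligibility and dedup.** Ancestry is classified from the four
  grandparental labels: full (4/4 matching the target population), mixed
  (1–3), ineligible (0). One sibling per family is retained, chosen
  uniformly under a seed.
- **Frequencies.** Percents round half-up to two decimals — verified
  exhaustively against all 33×2 + 22×3 printed table entries. Intervals
  are Wilson 95% score intervals, chosen over Wald for sane behavior at
  zero counts (several table rows are 0/3401 or 1/3401).
- **Couple risk.** `Σ_g f_g²` with variant fractions summed within genes
  before squaring; invariant to row order and to splitting a gene's
  carriers across rows, and checked against a two-draw Monte-Carlo oracle
  (the sum-of-squares is the union probability up to a negligible
  multi-gene overlap term). On the mixed-cohort table (uniform n = 3401)
  this gives 5.53×10⁻⁴ → 0.06%. On the small-cohort table the published
  0.82% is **not** recomputable: per-variant denominators range from 93 to
  438, so the aggregation behind the printed figure is underdetermined;
  the package reports its own value under the stated rule (≈0.92%) and the
  tests deliberately do not assert the published number.
- **Panel filters.** The screening filter keeps variants whose two-decimal
  percent strictly exceeds a threshold (0.6% default). "Present in the
  comparison population" is likewise operationalized at the tables'
  printed resolution — percent rounds above 0.00 — because three variants
  with a single carrier among ~50,000 round to 0.00% and are excluded,
  which is exactly what reproduces the published 16-variant count; a
  raw-count mode (≥1 carrier, giving 19) is available behind a flag.
- **Any-carrier rate.** The fraction of individuals carrying ≥1 panel
  variant is an operation on individual-level genotype matrices (simulated
  or called). The published 8.2% figure depended on individual-level data
  across all 40 screened variants, which was not released, so the package
  computes the statistic but asserts only its consistency with the
  independence prediction `1 − Π(1 − cf_i)` on simulated cohorts.

## Problem sizes used in the test suite

The shipped suite simulates, screens and verifies: a 3,401-individual
cohort at the mixed-cohort table frequencies (21 SNV/indel amplicons plus
the repeat locus, depth 100, error 0.3%) for parameter recovery — every
recovered frequency within its Wilson 95% interval of the realized truth
and genotype concordance ≥ 99.9%; a 5,000-individual cohort over a
6-variant sub-panel at depth 100 / error 0.1% for the generator-level
recovery contract; and 100 expansion carriers plus 367 non-carriers at
depth 50 for repeat-caller sensitivity (100/100) and specificity (0/367).
These sizes match the study's cohort scale while keeping a full run of the
suite in the low minutes on one CPU.

## Known limitations

- The genotyper is a deliberately simple threshold caller: no base-quality
  model, no local haplotype assembly, no multi-allelic sites, no CNV
  calling. It stands in for a production caller only to the extent the
  published quantities depend on het/hom classification.
- The repeat caller reports carrier state from per-read counts; it does not
  estimate expansion length, interpret premutation ranges, or emulate
  repeat-primed PCR validation.
- Synthetic amplicon and flank sequences are random stand-ins with the
  documented invariants; positional effects of the true genomic context
  (secondary structure, homopolymers near primers) are out of model.
- Fixture-derived statistics inherit the printed tables' resolution; no
  liftover, ClinVar/OMIM lookups, or re-curation is attempted.
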