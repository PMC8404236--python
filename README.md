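# ampliscreen

Targeted amplicon carrier screening for founder populations: a tested,
reusable implementation of a premarital-screening analysis pipeline —
multiplex amplicon read simulation, panel SNV/indel genotyping, GAA
repeat-expansion carrier detection at the *FXN* intron-1 locus (Friedreich
ataxia), and the cohort statistics a screening program publishes.

## Who this is for

Groups running (or studying) recessive-disease carrier screening in founder
populations — here modeled on cohorts of Syrian and Iranian Jewish ancestry
screened for a 40-variant panel — who need the published numbers to be
recomputable and the read-level algorithms to be testable without access to
the original raw sequencing data, which was never deposited. Every stage is
therefore exercised end to end on synthetic cohorts whose statistical
structure (Hardy–Weinberg genotypes at published carrier frequencies,
sibships, grandparental ancestry, repeat-length distributions) matches the
study design.

## The methods at the core

**Carrier frequency.** For a variant carried by $k$ of $n$ genotyped
individuals, the carrier frequency is $\hat f = k/n$, printed as a percent
rounded half-up to two decimals, with a Wilson 95% score interval.

**At-risk couple probability.** Under random mating, a couple is at risk
when both partners carry pathogenic variants in the same gene. With
per-gene carrier fractions $f_g$ (variant fractions summed within a gene),

$$P(\text{at-risk couple}) = \sum_g f_g^2 .$$

On the mixed-ancestry cohort table this evaluates to $5.53\times10^{-4}$,
i.e. 0.06% — about 6 of every 10,000 couples.

**Repeat-expansion calling (RPRF).** Reads from the *FXN* amplicon are
classified in sequence space, mirroring a decoy-reference mapping strategy:
a *split read* carries both a GAA-motif run and a ≥20 bp anchor matching the
non-repeat flank (the flank→repeat junction); a *pure repeat* read is GAA
tract only. For each repeat-bearing read the repeat-per-read frequency
(RPRF) is the longest tandem GAA run in triplets, scanning all three phase
rotations (GAA/AAG/AGA). A sample is a **carrier** when at least two of its
top-3 RPRF values strictly exceed 35 triplets; otherwise it is a
non-carrier. A sample at exactly (35, 35, 35) is a non-carrier.

**Genotyping.** Reads are assigned to amplicons by shared k-mers, aligned
by affine-gap dynamic programming (match +1, mismatch −1, gap open −3,
extend −1; global in the read, free target end gaps), and genotyped by a
threshold pileup caller: alt fraction < 0.20 hom-ref, 0.20–0.80 het,
> 0.80 hom-alt, fewer than 20 informative reads no-call. Indel support
requires the full printed alt allele in the aligned read.

## Worked example

Recompute the mixed-cohort screening statistics from the packaged
frequency table:

```bash
ampliscreen stats --table 3
```

prints (abridged):

```
Screening report - population: syrian_mixed
variants estimated: 22  genes: 20
at-risk couple probability: 0.000553 (5.5 per 10,000 couples; 0.06%)
variant                     carriers/n  percent  95% CI
COL6A2:c.1402C>T               56/3401     1.65  [1.27%, 2.13%]
GJB2:c.167del                  41/3401     1.21  [0.89%, 1.63%]
GNE:c.2228T>C                  24/3401     0.71  [0.47%, 1.05%]
FXN:GAA expansion              19/3401     0.56  [0.36%, 0.87%]
...
```

Each row is one panel variant: 56 of 3,401 mixed-ancestry individuals carry
the COL6A2 nonsense variant (1.65%, the cohort's most frequent allele), and
summing fractions within genes and squaring gives the 0.06% at-risk-couple
probability. A full simulated round trip — cohort → FASTQ → genotypes →
repeat calls → report:

```bash
ampliscreen simulate --seed 1 --n-families 200 --depth 100 --out-dir scratch/sim
ampliscreen screen --fastq scratch/sim/reads.fastq --seed 1 --out-dir scratch/screened
```

`screen` writes per-sample genotype calls (TSV and minimal VCF), the
repeat-expansion final report (sample, repeat-bearing read count, total
repeats, top-3 RPRF, carrier call), and a cohort `screening_report.json`;
estimated frequencies land within their Wilson intervals of the simulated
truth. `ampliscreen reproduce-paper` checks every fixture-derived statistic
(row counts, distinct-condition counts, the >0.6% screening-panel filter,
cross-population sharing, couple risks) and exits non-zero if any check or
fixture checksum fails.

## Layout

- `src/ampliscreen/panel.py` — variant panel model, fixture tables, synthetic amplicon references
- `src/ampliscreen/simulate.py` — cohort and read simulation (HWE genotypes, sibships, repeat alleles)
- `src/ampliscreen/genotype.py` — k-mer assignment, affine-gap alignment, threshold pileup caller
- `src/ampliscreen/frda.py` — GAA repeat counting, split-read classification, RPRF carrier rule
- `src/ampliscreen/stats.py` — cohort rules and published statistics, `reproduce-paper` checks
- `src/ampliscreen/pipeline.py` — per-sample screening orchestration and writers
- `src/ampliscreen/cli.py` — `simulate`, `screen`, `frda`, `stats`, `reproduce-paper`
- `docs/methods.md` — model assumptions, parameter choices, numerical details, limitations
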