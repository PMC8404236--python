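"""Synthetic cohorts and amplicon reads with the structure the screen assumes.

The generator emulates a premarital screening cohort: families with one or
more siblings, four grandparental ancestry labels per family, diploid panel
genotypes drawn under Hardy-Weinberg equilibrium from published carrier
frequencies, and a two-allele GAA repeat length at the FXN intron-1 locus.
Reads are single-end amplicon reads with uniform start positions, Poisson
per-amplicon depth, and substitution-only sequencing errors.

Carrier frequency ``cf`` (fraction of individuals with >= 1 alt allele) is
converted to an allele frequency by the exact HWE inversion
``q = 1 - sqrt(1 - cf)``; genotypes are then hom-alt with probability q^2
and het with probability 2q(1-q). The same conversion drives the per-allele
expansion probability at the repeat locus.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .panel import AmpliconTarget, VariantDef, alt_haplotype

__all__ = [
    "IndividualTruth",
    "SimConfig",
    "carrier_to_allele_freq",
    "simulate_cohort",
    "ReadSimulator",
    "simulate_reads",
    "write_fastq",
    "write_truth_tables",
]

ANCESTRIES = ("syrian", "iranian", "ashkenazi", "other")

# read must be able to hold >35 countable triplets plus two flank anchors
_MIN_COUNTABLE = 3 * 36


def carrier_to_allele_freq(cf: float) -> float:
    """Exact HWE inversion of a carrier frequency: ``q = 1 - sqrt(1 - cf)``."""
    if not 0.0 <= cf <= 1.0:
        raise ValueError(f"carrier frequency {cf} outside [0, 1]")
    return 1.0 - math.sqrt(1.0 - cf)


@dataclass(frozen=True)
class IndividualTruth:
    """Ground truth for one simulated person."""

    sample_id: str
    family_id: str
    grandparent_ancestries: tuple[str, str, str, str]
    panel_genotypes: Mapping[str, int]  # variant_id -> alt copies in {0,1,2}
    frda_alleles: tuple[int, int]  # GAA triplets per allele

    def __post_init__(self) -> None:
        if len(self.grandparent_ancestries) != 4:
            raise ValueError("exactly 4 grandparent ancestries required")
        if any(a not in ANCESTRIES for a in self.grandparent_ancestries):
            raise ValueError(f"unknown ancestry in {self.grandparent_ancestries}")
        if any(a < 1 for a in self.frda_alleles):
            raise ValueError("FRDA allele lengths must be >= 1 triplet")

    def carries(self, variant_id: str) -> bool:
        return self.panel_genotypes.get(variant_id, 0) > 0


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for cohort and read simulation.

    ``allele_freqs`` maps variant_id to a *carrier* frequency (the quantity
    the published tables report); ``sibs_per_family`` is the probability of
    a family having 1, 2, ... siblings. Defaults mirror the screening assay:
    250 bp single-end reads, Poisson(100) per-amplicon depth, substitution
    errors at 0.3%, normal repeat alleles uniform on [8, 30] triplets and
    expanded alleles uniform on [70, 1000].
    """

    seed: int
    n_families: int = 100
    sibs_per_family: tuple[float, ...] = (1.0,)
    allele_freqs: Mapping[str, float] = field(default_factory=dict)
    frda_normal_range: tuple[int, int] = (8, 30)
    frda_expanded_range: tuple[int, int] = (70, 1000)
    expansion_carrier_prob: float = 0.0
    ancestry_probs: Mapping[str, float] = field(
        default_factory=lambda: {"syrian": 0.55, "iranian": 0.15, "ashkenazi": 0.20, "other": 0.10}
    )
    read_length: int = 250
    depth_per_amplicon: float = 100.0
    substitution_error_rate: float = 0.003
    anchor_len: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        probs = list(self.allele_freqs.values()) + [
            self.expansion_carrier_prob, self.substitution_error_rate,
            *self.sibs_per_family, *self.ancestry_probs.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.sibs_per_family) - 1.0) > 1e-9:
            raise ValueError("sibs_per_family must sum to 1")
        if abs(sum(self.ancestry_probs.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry_probs must sum to 1")
        for lo, hi in (self.frda_normal_range, self.frda_expanded_range):
            if not 1 <= lo <= hi:
                raise ValueError("repeat ranges must satisfy 1 <= lo <= hi")
        if self.read_length < _MIN_COUNTABLE + 2 * self.anchor_len:
            raise ValueError(
                f"read_length must be >= {_MIN_COUNTABLE + 2 * self.anchor_len} "
                "(>35 countable triplets plus two flank anchors)"
            )
        if self.depth_per_amplicon < 0:
            raise ValueError("depth_per_amplicon must be >= 0")


def _genotype_draws(rng: np.random.Generator, cf: float, n: int) -> np.ndarray:
    """Alt-copy counts for ``n`` individuals under exact HWE."""
    q = carrier_to_allele_freq(cf)
    u = rng.random(n)
    copies = np.zeros(n, dtype=np.int8)
    copies[u < q * q] = 2
    copies[(u >= q * q) & (u < q * q + 2 * q * (1 - q))] = 1
    return copies


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> list[IndividualTruth]:
    """Draw a cohort of families with genotypes, ancestries and repeat alleles.

    Siblings share a family id and grandparental ancestries; genotypes are
    drawn independently per individual (the screen never uses within-family
    genotype correlation, only the one-sibling-per-family dedup rule).
    Deterministic under a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sib_probs = np.asarray(config.sibs_per_family, dtype=float)
    ancestry_names = tuple(config.ancestry_probs)
    ancestry_p = np.asarray([config.ancestry_probs[a] for a in ancestry_names], dtype=float)

    sample_ids: list[str] = []
    family_ids: list[str] = []
    ancestries: list[tuple[str, str, str, str]] = []
    for fam in range(config.n_families):
        family_id = f"F{fam:05d}"
        n_sibs = int(rng.choice(len(sib_probs), p=sib_probs)) + 1
        gps = tuple(ancestry_names[i] for i in rng.choice(len(ancestry_names), size=4, p=ancestry_p))
        for j in range(n_sibs):
            sample_ids.append(f"{family_id}_S{j}")
            family_ids.append(family_id)
            ancestries.append(gps)

    n = len(sample_ids)
    genotypes = {
        vid: _genotype_draws(rng, cf, n) for vid, cf in config.allele_freqs.items()
    }

    q_exp = carrier_to_allele_freq(config.expansion_carrier_prob)
    expanded = rng.random((n, 2)) < q_exp
    lo_n, hi_n = config.frda_normal_range
    lo_e, hi_e = config.frda_expanded_range
    lengths = rng.integers(lo_n, hi_n + 1, size=(n, 2))
    if q_exp > 0:
        lengths[expanded] = rng.integers(lo_e, hi_e + 1, size=int(expanded.sum()))

    people = []
    for i in range(n):
        people.append(
            IndividualTruth(
                sample_id=sample_ids[i],
                family_id=family_ids[i],
                grandparent_ancestries=ancestries[i],
                panel_genotypes={vid: int(g[i]) for vid, g in genotypes.items()},
                frda_alleles=(int(lengths[i, 0]), int(lengths[i, 1])),
            )
        )
    return people


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_ERR_LOOKUP = np.zeros((256, 3), dtype=np.uint8)
for _b, _alts in zip(b"ACGT", (b"CGT", b"AGT", b"ACT", b"ACG")):
    _ERR_LOOKUP[_b] = np.frombuffer(_alts, dtype=np.uint8)


def _inject_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Substitute random bases in-place at the given per-base rate."""
    if error_rate <= 0 or reads.size == 0:
        return
    n_err = rng.binomial(reads.size, error_rate)
    if n_err == 0:
        return
    flat = rng.choice(reads.size, size=n_err, replace=False)
    view = reads.reshape(-1)
    view[flat] = _ERR_LOOKUP[view[flat], rng.integers(0, 3, size=n_err)]


def _windows(seq: np.ndarray, depth: float, read_len: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly placed read windows over one haplotype sequence."""
    n = rng.poisson(depth)
    read_len = min(read_len, len(seq))
    if n == 0:
        return np.empty((0, read_len), dtype=np.uint8)
    starts = rng.integers(0, len(seq) - read_len + 1, size=n)
    return seq[starts[:, None] + np.arange(read_len)[None, :]]


class ReadSimulator:
    """Batched amplicon read generator for one panel.

    Precomputes ref/alt haplotype byte arrays per amplicon and the two flank
    halves of the repeat locus, then emits per-sample batches of reads as
    ``(amplicon_id, uint8 array)`` pairs — the form the screening pipeline
    consumes directly; FASTQ serialization is a separate, optional step.
    """

    FXN_AMPLICON_ID = "amp_FXN"

    def __init__(
        self,
        panel: Sequence[VariantDef],
        amplicons: Sequence[AmpliconTarget],
        config: SimConfig,
        flank_seq: str | None = None,
    ) -> None:
        self.config = config
        self.amplicons = list(amplicons)
        by_id = {v.variant_id: v for v in panel}
        self._haps: list[tuple[str, np.ndarray, np.ndarray, str]] = []
        for amp in self.amplicons:
            (vid,) = amp.target_variant_ids  # one variant per synthetic amplicon
            variant = by_id[vid]
            if not variant.is_genotypable:
                raise ValueError(f"{vid}: not a read-genotypable variant")
            ref_hap = np.frombuffer(amp.local_ref_seq.encode(), dtype=np.uint8)
            alt_hap = np.frombuffer(alt_haplotype(amp, variant).encode(), dtype=np.uint8)
            self._haps.append((amp.amplicon_id, ref_hap, alt_hap, vid))
        self._flank = flank_seq
        if flank_seq is not None:
            half = len(flank_seq) // 2
            self._flank_left = flank_seq[:half].encode()
            self._flank_right = flank_seq[half:].encode()

    def frda_haplotype(self, n_triplets: int) -> np.ndarray:
        if self._flank is None:
            raise ValueError("no repeat-locus flank sequence configured")
        seq = self._flank_left + b"GAA" * n_triplets + self._flank_right
        return np.frombuffer(seq, dtype=np.uint8)

    def sample_batches(
        self, person: IndividualTruth, rng: np.random.Generator
    ) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (amplicon_id, reads) batches for one person."""
        cfg = self.config
        for amp_id, ref_hap, alt_hap, vid in self._haps:
            copies = person.panel_genotypes.get(vid, 0)
            haps = {0: (ref_hap,), 1: (ref_hap, alt_hap), 2: (alt_hap,)}[copies]
            per_hap_depth = cfg.depth_per_amplicon / len(haps)
            for hap in haps:
                reads = _windows(hap, per_hap_depth, cfg.read_length, rng)
                _inject_errors(reads, cfg.substitution_error_rate, rng)
                if len(reads):
                    yield amp_id, reads
        if self._flank is not None:
            for allele in person.frda_alleles:
                hap = self.frda_haplotype(allele)
                reads = _windows(hap, cfg.depth_per_amplicon / 2, cfg.read_length, rng)
                _inject_errors(reads, cfg.substitution_error_rate, rng)
                if len(reads):
                    yield self.FXN_AMPLICON_ID, reads


def _person_rng(config: SimConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(sample_id.encode())])
    )


def simulate_reads(
    person: IndividualTruth,
    panel: Sequence[VariantDef],
    amplicons: Sequence[AmpliconTarget],
    config: SimConfig,
    flank_seq: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Simulate one person's reads as ``(read_id, sequence)`` records.

    Read ids encode the sample, source amplicon and serial index
    (``sample|amplicon|i``). With no ``rng``, a stream derived from the
    config seed and the sample id is used, so per-person output does not
    depend on cohort order.
    """
    if rng is None:
        rng = _person_rng(config, person.sample_id)
    sim = ReadSimulator(panel, amplicons, config, flank_seq=flank_seq)
    records = []
    i = 0
    for amp_id, reads in sim.sample_batches(person, rng):
        for row in reads:
            records.append((f"{person.sample_id}|{amp_id}|{i}", row.tobytes().decode()))
            i += 1
    return records


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(read_id, seq)`` records as 4-line FASTQ; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_truth_tables(people: Sequence[IndividualTruth], outdir: str | Path, header: str = "") -> None:
    """Write the truth sidecars: individuals.tsv, genotypes.tsv, frda_truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "individuals.tsv", "w") as fh:
        if header:
            fh.write(header)
        fh.write("sample_id\tfamily_id\tgp1\tgp2\tgp3\tgp4\n")
        for p in people:
            fh.write(f"{p.sample_id}\t{p.family_id}\t" + "\t".join(p.grandparent_ancestries) + "\n")
    with open(outdir / "genotypes.tsv", "w") as fh:
        if header:
            fh.write(header)
        fh.write("sample_id\tvariant_id\talt_copies\n")
        for p in people:
            for vid, copies in sorted(p.panel_genotypes.items()):
                if copies:
                    fh.write(f"{p.sample_id}\t{vid}\t{copies}\n")
    with open(outdir / "frda_truth.tsv", "w") as fh:
        if header:
            fh.write(header)
        fh.write("sample_id\tallele1\tallele2\n")
        for p in people:
            fh.write(f"{p.sample_id}\t{p.frda_alleles[0]}\t{p.frda_alleles[1]}\n")
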