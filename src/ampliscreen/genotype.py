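"""Diploid genotype calling at panel SNV/indel sites from amplicon reads.

A deliberately transparent three-stage caller: k-mer based read-to-amplicon
assignment, gapped alignment of each read against its amplicon's local
reference, and a threshold pileup caller on allele-supporting depths.

Scoring and thresholds are fixed and documented so every call is exactly
reproducible: alignment is scored match +1, mismatch -1, gap open -3, gap
extend -1 (the opening base costs -3), reads scoring below ``-0.2 * read
length`` are discarded from the pileup, indel support requires the full alt
allele string in the aligned read, the het band is [0.20, 0.80] on the alt
fraction, and sites with fewer than 20 ref+alt reads are no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import AmpliconTarget, VariantDef

__all__ = [
    "AlleleDepths",
    "GenotypeCall",
    "Alignment",
    "assign_read_to_amplicon",
    "align_read",
    "read_segment",
    "pileup_depths",
    "call_from_depths",
    "pileup_and_call",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_HET_BAND",
]

DEFAULT_MIN_DEPTH = 20
DEFAULT_HET_BAND = (0.20, 0.80)
GENOTYPES = ("hom_ref", "het", "hom_alt", "no_call")


@dataclass(frozen=True)
class AlleleDepths:
    """Read support at one site: ref-, alt- and other-supporting depths."""

    variant_id: str
    sample_id: str
    ref_depth: int
    alt_depth: int
    other_depth: int

    def __post_init__(self) -> None:
        if min(self.ref_depth, self.alt_depth, self.other_depth) < 0:
            raise ValueError("depths must be non-negative")

    @property
    def informative_depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class GenotypeCall:
    variant_id: str
    sample_id: str
    genotype: str  # one of GENOTYPES
    alt_fraction: float | None  # None when informative depth is 0
    depths: AlleleDepths | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def is_carrier(self) -> bool:
        return self.genotype in ("het", "hom_alt")


# ---------------------------------------------------------------------------
# Read -> amplicon assignment
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def assign_read_to_amplicon(
    read: str,
    amplicons: Sequence[AmpliconTarget],
    k: int = 21,
    min_shared: int = 3,
) -> str | None:
    """Assign a read to the amplicon sharing the most k-mers with it.

    Returns the winning ``amplicon_id``, or ``None`` when the best overlap
    is below ``min_shared`` k-mers or tied between amplicons.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    read_kmers = _kmers(read.upper(), k)
    best_id, best, runner_up = None, 0, 0
    for amp in amplicons:
        shared = len(read_kmers & _kmers(amp.local_ref_seq, k))
        if shared > best:
            best_id, best, runner_up = amp.amplicon_id, shared, best
        elif shared == best:
            runner_up = shared
    if best < min_shared or best == runner_up:
        return None
    return best_id


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A gapped placement of a read on an amplicon reference.

    ``offset`` is the 0-based target start; ``ops`` is a CIGAR-like op list
    over ('=', 'X', 'I', 'D') where I consumes read only and D consumes
    target only (read-as-query convention).
    """

    offset: int
    ops: tuple[tuple[str, int], ...]
    score: int

    @property
    def target_span(self) -> tuple[int, int]:
        end = self.offset + sum(l for op, l in self.ops if op in "=XD")
        return self.offset, end


def alignment_score(
    ops: Iterable[tuple[str, int]],
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -3,
    gap_extend: int = -1,
) -> int:
    score = 0
    for op, length in ops:
        if op == "=":
            score += match * length
        elif op == "X":
            score += mismatch * length
        elif op in "ID":
            score += gap_open + gap_extend * (length - 1)
        else:
            raise ValueError(f"unknown op {op!r}")
    return score


_NEG = -(10 ** 6)
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1, -1, -3, -1


def _gotoh_matrices(read: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine-gap DP, global in the read with free target end gaps.

    Three-state Gotoh recurrences, one vectorized pass per read base; the
    horizontal (target-consuming) gap state uses a running-maximum since the
    affine cost is linear in gap length.
    """
    m, n = len(read), len(target)
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in target (read consumed)
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in read (target consumed)
    M[0, :] = 0  # alignment may start at any target position for free
    j_idx = np.arange(1, n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(target == read[i - 1], _MATCH, _MISMATCH).astype(np.int32)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        Ix[i] = np.maximum(
            np.maximum(M[i - 1], Iy[i - 1]) + _GAP_OPEN, Ix[i - 1] + _GAP_EXTEND
        )
        # Iy[i, j] = max_{k<j} (max(M,Ix)[i, k] + open + (j-k-1)*extend)
        origin = np.maximum(M[i], Ix[i]) + _GAP_OPEN - _GAP_EXTEND * j_idx[0]
        running = np.maximum.accumulate(origin[:-1] - _GAP_EXTEND * np.arange(n))
        Iy[i, 1:] = running + _GAP_EXTEND * j_idx
    return M, Ix, Iy


def _traceback(
    read: str, target: str, M: np.ndarray, Ix: np.ndarray, Iy: np.ndarray
) -> tuple[int, tuple[tuple[str, int], ...], int]:
    m = len(read)
    finals = np.maximum(M[m], Ix[m])  # a trailing deletion never helps
    j = int(np.argmax(finals))  # leftmost end on ties
    score = int(finals[j])
    state = "M" if M[m, j] >= Ix[m, j] else "Ix"
    i = m
    raw: list[str] = []
    while i > 0:
        if state == "M":
            raw.append("=" if read[i - 1] == target[j - 1] else "X")
            prev = M[i, j] - (_MATCH if raw[-1] == "=" else _MISMATCH)
            i, j = i - 1, j - 1
            # deterministic preference on ties: diagonal, then read gap, then target gap
            state = "M" if M[i, j] == prev else ("Iy" if Iy[i, j] == prev else "Ix")
        elif state == "Ix":
            raw.append("I")
            if Ix[i, j] == Ix[i - 1, j] + _GAP_EXTEND:
                state = "Ix"
            else:
                prev = Ix[i, j] - _GAP_OPEN
                state = "M" if M[i - 1, j] == prev else "Iy"
            i -= 1
        else:  # Iy
            raw.append("D")
            if Iy[i, j] == Iy[i, j - 1] + _GAP_EXTEND:
                state = "Iy"
            else:
                prev = Iy[i, j] - _GAP_OPEN
                state = "M" if M[i, j - 1] == prev else "Ix"
            j -= 1
    ops: list[tuple[str, int]] = []
    for op in reversed(raw):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return j, tuple(ops), score


def align_read(
    read: str,
    target: AmpliconTarget | str,
    score_floor_factor: float = -0.2,
) -> Alignment | None:
    """Align a read end-to-end against a local amplicon reference.

    Global in the read, free end gaps in the target ("infix" alignment),
    scored by affine-gap dynamic programming under the declared scheme.
    Ties prefer the leftmost alignment (smallest end position, diagonal
    moves first in the traceback). Reads scoring below
    ``score_floor_factor * len(read)`` (default -0.2 per base) are
    discarded, returning ``None``.
    """
    ref = target.local_ref_seq if isinstance(target, AmpliconTarget) else target
    read = read.upper()
    if not read or not ref:
        return None
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    M, Ix, Iy = _gotoh_matrices(read_arr, ref_arr)
    end_j, ops, score = _traceback(read, ref, M, Ix, Iy)
    if score < score_floor_factor * len(read):
        return None
    return Alignment(offset=end_j, ops=ops, score=score)


def read_segment(read: str, alignment: Alignment, span: tuple[int, int]) -> str | None:
    """Read bases aligned to the target interval ``span`` = [a, b).

    Insertions at internal junctions and at the right edge of the span are
    included (so an anchored insertion alt like T->TA is recoverable from a
    single anchor base); deleted target bases contribute nothing. Returns
    ``None`` when the alignment does not fully cover the span.
    """
    a, b = span
    t0, t1 = alignment.target_span
    if t0 > a or t1 < b:
        return None
    t, r = alignment.offset, 0
    out: list[str] = []
    for op, length in alignment.ops:
        if op in "=X":
            lo, hi = max(t, a), min(t + length, b)
            if lo < hi:
                out.append(read[r + (lo - t): r + (hi - t)])
            t += length
            r += length
        elif op == "D":
            t += length
        elif op == "I":
            if a < t <= b:
                out.append(read[r:r + length])
            r += length
    return "".join(out)


# ---------------------------------------------------------------------------
# Pileup and genotype call
# ---------------------------------------------------------------------------

def classify_support(read: str, alignment: Alignment, variant: VariantDef, offset: int) -> str | None:
    """Classify one aligned read as 'ref', 'alt' or 'other' at a site.

    ``None`` when the read does not span the ref-allele interval. Alt
    support requires the full printed alt allele string, so partial indel
    overlaps count as 'other'.
    """
    seg = read_segment(read, alignment, (offset, offset + len(variant.ref)))
    if seg is None:
        return None
    if seg == variant.ref:
        return "ref"
    if seg == variant.alt:
        return "alt"
    return "other"


def pileup_depths(
    aligned_reads: Iterable[tuple[str, Alignment]],
    variant: VariantDef,
    offset: int,
    sample_id: str = "",
) -> AlleleDepths:
    counts = {"ref": 0, "alt": 0, "other": 0}
    for read, alignment in aligned_reads:
        support = classify_support(read, alignment, variant, offset)
        if support is not None:
            counts[support] += 1
    return AlleleDepths(variant.variant_id, sample_id, counts["ref"], counts["alt"], counts["other"])


def call_from_depths(
    depths: AlleleDepths,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> GenotypeCall:
    """Threshold genotype call from allele depths.

    no_call below ``min_depth`` informative (ref+alt) reads; otherwise
    hom_ref / het / hom_alt by the alt fraction against the het band
    (inclusive at both band edges).
    """
    informative = depths.informative_depth
    alt_fraction = depths.alt_depth / informative if informative else None
    if informative < min_depth:
        genotype = "no_call"
    elif alt_fraction < het_band[0]:
        genotype = "hom_ref"
    elif alt_fraction <= het_band[1]:
        genotype = "het"
    else:
        genotype = "hom_alt"
    return GenotypeCall(depths.variant_id, depths.sample_id, genotype, alt_fraction, depths)


def pileup_and_call(
    aligned_reads: Iterable[tuple[str, Alignment]],
    variant: VariantDef,
    offset: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    sample_id: str = "",
) -> GenotypeCall:
    """Pile aligned reads on one variant site and call the diploid genotype."""
    depths = pileup_depths(aligned_reads, variant, offset, sample_id=sample_id)
    return call_from_depths(depths, min_depth=min_depth, het_band=het_band)
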