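"""Read assignment, gapped alignment, and threshold genotype calling."""

import numpy as np
import pytest

from ampliscreen.genotype import (
    AlleleDepths,
    align_read,
    alignment_score,
    assign_read_to_amplicon,
    call_from_depths,
    pileup_and_call,
    read_segment,
)
from ampliscreen.panel import alt_haplotype


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kmer_overlap_argmax(read, amplicons, k):
    """Brute-force shared-k-mer count; (best_id, best, runner_up)."""
    def kmers(s):
        return {s[i:i + k] for i in range(len(s) - k + 1)}
    counts = {a.amplicon_id: len(kmers(read) & kmers(a.local_ref_seq)) for a in amplicons}
    ranked = sorted(counts.items(), key=lambda kv: -kv[1])
    return ranked[0][0], ranked[0][1], ranked[1][1] if len(ranked) > 1 else 0


def best_infix_score(read, target):
    """Exhaustive best affine score of global-in-read, free-target-ends alignments.

    Enumerates every monotone op path (tiny inputs only) under the declared
    scheme: match +1, mismatch -1, gap open -3, extend -1.
    """
    best = -10 ** 9

    def go(i, j, score, last_op):
        nonlocal best
        if i == len(read):
            best = max(best, score)
            return
        if j < len(target):
            s = 1 if read[i] == target[j] else -1
            go(i + 1, j + 1, score + s, "M")
        # insertion in read (consumes read only)
        go(i + 1, j, score + (-1 if last_op == "I" else -3), "I")
        # deletion (consumes target only)
        if j < len(target):
            go(i, j + 1, score + (-1 if last_op == "D" else -3), "D")

    for start in range(len(target) + 1):
        go(0, start, 0, None)
    return best


def rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

class TestAssignment:
    def test_exact_prefix_assigns_to_source(self, amplicons):
        amp = amplicons[0]
        assert assign_read_to_amplicon(amp.local_ref_seq[:120], amplicons) == amp.amplicon_id

    def test_unrelated_read_unassigned(self, amplicons):
        rng = np.random.default_rng(1)
        read = rng_seq(rng, 150)  # random 150-mers share no 21-mers with the panel
        assert assign_read_to_amplicon(read, amplicons) is None

    def test_two_substitutions_still_assigns(self, amplicons):
        amp = amplicons[3]
        read = list(amp.local_ref_seq[50:200])
        read[30] = "A" if read[30] != "A" else "C"
        read[100] = "A" if read[100] != "A" else "C"
        read = "".join(read)
        expected, best, runner = kmer_overlap_argmax(read, amplicons, 15)
        assert best >= 3 and best > runner  # oracle confirms an unambiguous winner
        assert assign_read_to_amplicon(read, amplicons, k=15) == expected == amp.amplicon_id

    def test_tie_is_unassigned(self, amplicons):
        # a read present verbatim in two amplicons ties and is dropped
        a, b = amplicons[0], amplicons[1]
        shared = a.local_ref_seq[:60]
        fake_b = type(b)(
            amplicon_id="amp_fake",
            target_variant_ids=b.target_variant_ids,
            local_ref_seq=shared + b.local_ref_seq[60:],
            variant_offsets=b.variant_offsets,
        )
        assert assign_read_to_amplicon(shared, [a, fake_b]) is None

    def test_small_k_rejected(self, amplicons):
        with pytest.raises(ValueError):
            assign_read_to_amplicon("ACGT" * 10, amplicons, k=7)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

class TestAlignment:
    def test_identical_window_scores_read_length(self, amplicons):
        amp = amplicons[0]
        read = amp.local_ref_seq[37:37 + 150]
        aln = align_read(read, amp)
        assert aln.offset == 37
        assert aln.ops == (("=", 150),)
        assert aln.score == 150

    def test_single_deletion_recovered(self):
        target = "TTGACCTGATTACAGGCTTAGGCATT"
        read = target[3:10] + target[11:20]  # one base deleted
        aln = align_read(read, target)
        assert ("D", 1) in aln.ops
        assert aln.score == len(read) - 3
        assert alignment_score(aln.ops) == aln.score

    def test_matches_exhaustive_oracle_on_tiny_cases(self):
        rng = np.random.default_rng(7)
        for case in range(12):
            target = rng_seq(rng, 12)
            start = int(rng.integers(0, 5))
            read = list(target[start:start + 7])
            kind = case % 3
            if kind == 1 and len(read) > 2:  # substitution
                read[2] = "A" if read[2] != "A" else "G"
            if kind == 2:  # single deletion from the read
                del read[3]
            read = "".join(read)
            aln = align_read(read, target)
            assert aln is not None
            assert aln.score == best_infix_score(read, target)

    def test_all_n_read_discarded(self, amplicons):
        assert align_read("N" * 120, amplicons[0]) is None

    def test_leftmost_placement_on_repeated_window(self):
        target = "ACGTACGTTTTTACGTACGT"
        aln = align_read("ACGTACGT", target)
        assert aln.offset == 0

    def test_read_segment_requires_full_span(self):
        target = "AAAACCCCGGGGTTTT"
        aln = align_read("CCCCGGGG", target)
        assert read_segment("CCCCGGGG", aln, (2, 6)) is None  # starts before the read
        assert read_segment("CCCCGGGG", aln, (6, 10)) == "CCGG"


# ---------------------------------------------------------------------------
# pileup calling
# ---------------------------------------------------------------------------

def aligned_site_reads(amp, variant, n_ref, n_alt, length=120):
    """Error-free reads covering the variant site from ref and alt haplotypes."""
    off = amp.variant_offsets[variant.variant_id]
    start = max(0, off - length // 2)
    reads = []
    for hap, n in ((amp.local_ref_seq, n_ref), (alt_haplotype(amp, variant), n_alt)):
        window = hap[start:start + length]
        reads.extend([window] * n)
    return [(r, align_read(r, amp)) for r in reads]


class TestPileup:
    @pytest.mark.parametrize("n_ref, n_alt, expected", [
        (50, 0, "hom_ref"),
        (52, 48, "het"),   # alt fraction 0.48 sits inside the het band
        (0, 40, "hom_alt"),
        (5, 4, "no_call"),  # informative depth 9 < 20
    ])
    def test_snv_threshold_calls(self, panel_by_id, amplicons_by_id, n_ref, n_alt, expected):
        vid = "COL6A2:c.1402C>T"
        v, amp = panel_by_id[vid], amplicons_by_id[f"amp_{vid}"]
        call = pileup_and_call(aligned_site_reads(amp, v, n_ref, n_alt), v,
                               amp.variant_offsets[vid])
        assert call.genotype == expected

    @pytest.mark.parametrize("vid", [
        "CFTR:c.1521_1523del",   # ATCT -> A deletion
        "MMACHC:c.271dup",       # T -> TA insertion
        "USH2A:c.236_239dup",    # G -> GGTAC insertion
        "SMPD1:c.1826_1828GCC",  # TGCC -> T deletion
    ])
    def test_indel_alt_support_from_alignment(self, panel_by_id, amplicons_by_id, vid):
        v, amp = panel_by_id[vid], amplicons_by_id[f"amp_{vid}"]
        call = pileup_and_call(aligned_site_reads(amp, v, 30, 30), v,
                               amp.variant_offsets[vid])
        assert call.genotype == "het"
        assert call.depths.ref_depth == call.depths.alt_depth == 30

    def test_partial_indel_overlap_counts_other(self, panel_by_id, amplicons_by_id):
        vid = "CFTR:c.1521_1523del"
        v, amp = panel_by_id[vid], amplicons_by_id[f"amp_{vid}"]
        off = amp.variant_offsets[vid]
        # delete only 2 of the 3 bases: neither the ref nor the printed alt
        hap = amp.local_ref_seq
        partial = hap[:off + 1] + hap[off + 3:]
        read = partial[off - 60:off + 60]
        call = pileup_and_call([(read, align_read(read, amp))], v, off, min_depth=1)
        assert call.depths.other_depth == 1
        assert call.depths.alt_depth == call.depths.ref_depth == 0

    def test_depth_zero_has_undefined_fraction(self):
        call = call_from_depths(AlleleDepths("x", "s", 0, 0, 0))
        assert call.genotype == "no_call" and call.alt_fraction is None

    def test_het_band_edges_inclusive(self):
        assert call_from_depths(AlleleDepths("x", "s", 80, 20, 0)).genotype == "het"
        assert call_from_depths(AlleleDepths("x", "s", 20, 80, 0)).genotype == "het"
        assert call_from_depths(AlleleDepths("x", "s", 81, 19, 0)).genotype == "hom_ref"
        assert call_from_depths(AlleleDepths("x", "s", 19, 81, 0)).genotype == "hom_alt"
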