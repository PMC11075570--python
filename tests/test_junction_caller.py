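"""Universal-primer design, read simulation, and insertion-site calling."""

import numpy as np
import pytest

from morfin import (
    CallerConfig,
    DesignError,
    OrfAnnotation,
    PlasmidRecord,
    SangerRead,
    call_insertion,
    classify_event,
    design_amplicon,
    design_universal_primer,
    fixtures,
    insert_at,
    simulate_read,
)

VARIANTS = ("none", "extra3", "extra6")


@pytest.fixture(scope="module")
def fp_orf():
    return fixtures.synth_fp_orf(41, aa_len=110)


@pytest.fixture(scope="module")
def amplicon(fp_orf):
    return design_amplicon(fp_orf, "none", fp_name="fp")


@pytest.fixture(scope="module")
def plasmid():
    return fixtures.synth_plasmid(42, backbone_len=900, orf_len=600, label="tgt")


def plant_in_frame(plasmid, amplicon, codon_N):
    """An insertion whose true codon N is known by construction."""
    orf = plasmid.orfs[0]
    L = len(plasmid)
    orf_nt = orf.nt_length(L)
    if orf.strand == "+":
        cut = orf.start + 3 * codon_N
        orientation = "forward"
    else:
        d = orf_nt - 3 * codon_N - 9
        cut = (orf.start + d) % L
        orientation = "reverse"
    return insert_at(plasmid, amplicon, cut, orientation)


class TestUniversalPrimer:
    def test_primer_is_coding_strand_substring(self, amplicon):
        primer = design_universal_primer(amplicon, offset=60)
        assert len(primer) == 20
        assert primer in amplicon.sequence

    def test_primer_position(self, amplicon):
        primer = design_universal_primer(amplicon, offset=60, length=20)
        end = amplicon.sequence.index(primer) + len(primer)
        assert amplicon.fp_core_end - end == 60

    def test_offset_beyond_fp_rejected(self, amplicon):
        with pytest.raises(DesignError):
            design_universal_primer(amplicon, offset=10_000)

    def test_read_covers_junction(self, plasmid, amplicon):
        ev = plant_in_frame(plasmid, amplicon, 40)
        read = simulate_read(ev)
        assert read.source == "simulated"
        # 3' linker, element, and downstream target flank all present
        from morfin import ME_ELEMENT, revcomp

        assert revcomp(ME_ELEMENT) in read.sequence
        tail = read.sequence.split(revcomp(ME_ELEMENT))[1]
        assert len(tail) > 100


class TestRoundTrip:
    @pytest.mark.parametrize("variant", VARIANTS)
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_error_free_reads_recover_planted_sites(self, fp_orf, variant, strand):
        plasmid = fixtures.synth_plasmid(43, 900, 600, label="tgt", strand=strand)
        amp = design_amplicon(fp_orf, variant, fp_name="fp")
        orf = plasmid.orfs[0]
        rng = np.random.default_rng(44)
        n_sense = orf.codon_count(len(plasmid)) - 1
        for codon_N in rng.integers(1, n_sense - 3, size=20):
            ev = plant_in_frame(plasmid, amp, int(codon_N))
            rep = classify_event(ev, plasmid, orf)
            assert rep.classification == "in_frame_candidate"
            assert rep.codon_N == codon_N
            call = call_insertion(simulate_read(ev), amp, plasmid, orf)
            assert call.status == "confirmed_in_frame"
            assert call.codon_N == codon_N
            assert call.duplicated_codons == rep.duplicated_codons

    def test_out_of_frame_event_is_a_frame_violation(self, plasmid, amplicon):
        orf = plasmid.orfs[0]
        ev = insert_at(plasmid, amplicon, orf.start + 3 * 40 + 1, "forward")
        call = call_insertion(simulate_read(ev), amplicon, plasmid, orf)
        assert call.status == "frame_violation"

    def test_wrong_orientation_read_maps_to_minus_strand(self, plasmid, amplicon):
        orf = plasmid.orfs[0]
        ev = insert_at(plasmid, amplicon, orf.start + 3 * 40, "reverse")
        call = call_insertion(simulate_read(ev), amplicon, plasmid, orf)
        assert call.status == "frame_violation"
        assert call.orientation == "-"

    def test_never_confirms_within_codon_cuts(self, plasmid, amplicon):
        orf = plasmid.orfs[0]
        for shift in (1, 2):
            for k in (10, 80, 150):
                ev = insert_at(plasmid, amplicon, orf.start + 3 * k + shift, "forward")
                call = call_insertion(simulate_read(ev), amplicon, plasmid, orf)
                assert call.status != "confirmed_in_frame"


class TestFailureModes:
    def test_backbone_read_has_no_element(self, plasmid, amplicon):
        read = SangerRead("bb", plasmid.sequence[:400])
        call = call_insertion(read, amplicon, plasmid, plasmid.orfs[0])
        assert call.status == "element_not_found"

    def test_short_flank_unmapped(self, plasmid, amplicon):
        ev = plant_in_frame(plasmid, amplicon, 40)
        full = simulate_read(ev).sequence
        from morfin import ME_ELEMENT, revcomp

        cutoff = full.index(revcomp(ME_ELEMENT)) + 19 + 10  # only 10 nt of flank
        call = call_insertion(
            SangerRead("short", full[:cutoff]), amplicon, plasmid, plasmid.orfs[0]
        )
        assert call.status == "flank_unmapped"

    def test_repeated_target_flank_is_ambiguous(self, amplicon):
        # an ORF with the same 30-nt block at two codon-aligned positions
        block = "GCAGCTGAAGCAACCGCTGCAGAAGCTACC"
        filler1 = "GATGAAGCT" * 5
        filler2 = "GAAGCTGCC" * 8
        orf = "ATG" + filler1 + block + filler2 + block + "GAAGCTGAT" * 4 + "TAA"
        assert len(orf) % 3 == 0
        backbone = str(
            PlasmidRecord("tmp", fixtures.synth_plasmid(45, 300, 30).sequence).sequence
        )[:300]
        plasmid = PlasmidRecord(
            "rep", backbone + orf, orfs=[OrfAnnotation("rep", 300, 300 + len(orf))]
        )
        codon_of_block1 = (3 + len(filler1)) // 3 + 1  # codon M where block 1 starts
        ev = plant_in_frame(plasmid, amplicon, codon_of_block1 - 1)
        call = call_insertion(simulate_read(ev), amplicon, plasmid, plasmid.orfs[0])
        assert call.status == "ambiguous"

    def test_n_bases_count_as_mismatches(self, plasmid, amplicon):
        ev = plant_in_frame(plasmid, amplicon, 40)
        seq = simulate_read(ev).sequence
        from morfin import ME_ELEMENT, revcomp

        flank_at = seq.index(revcomp(ME_ELEMENT)) + 19
        mutated = seq[: flank_at + 4] + "N" + seq[flank_at + 5 :]
        call = call_insertion(SangerRead("n", mutated), amplicon, plasmid, plasmid.orfs[0])
        assert call.status == "confirmed_in_frame"
        assert call.codon_N == 40
        assert call.mismatches <= 2


class TestErrorTolerance:
    def test_substitution_errors_mostly_tolerated(self, plasmid, amplicon):
        orf = plasmid.orfs[0]
        rng = np.random.default_rng(46)
        correct = 0
        n = 40
        for i in range(n):
            codon_N = int(rng.integers(1, orf.codon_count(len(plasmid)) - 5))
            ev = plant_in_frame(plasmid, amplicon, codon_N)
            read = simulate_read(ev, error_rate=0.005, rng=rng)
            call = call_insertion(read, amplicon, plasmid, orf)
            correct += call.status == "confirmed_in_frame" and call.codon_N == codon_N
        assert correct >= 0.9 * n
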