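"""Fusion classification: rule logic, brute-force oracle agreement, summaries."""

import warnings

import pytest

from morfin import (
    ConfigurationError,
    classify_event,
    design_amplicon,
    fixtures,
    insert_at,
    simulate_library,
    summarize_library,
    translate,
)

from _oracle import is_candidate, junction_marker_for

VARIANTS = ("none", "extra3", "extra6")


def _exhaustive(plasmid, amplicon):
    orf = plasmid.orfs[0]
    for cut in range(len(plasmid)):
        for orientation in ("forward", "reverse"):
            ev = insert_at(plasmid, amplicon, cut, orientation)
            yield ev, classify_event(ev, plasmid, orf)


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", VARIANTS)
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_cut_and_orientation_matches_brute_force(self, variant, strand):
        """Exhaustive agreement between the rule-based classifier and an
        independent assemble-and-translate oracle on a 300-bp plasmid."""
        plasmid = fixtures.synth_plasmid(21, 150, 150, label="toy", strand=strand)
        fp_orf = fixtures.synth_fp_orf(22, aa_len=25)
        amplicon = design_amplicon(fp_orf, variant)
        orf = plasmid.orfs[0]
        marker = junction_marker_for(fp_orf, amplicon.extra5)
        target_pep = translate(plasmid.orf_sense(orf))[:-1]

        n_classifier = n_oracle = 0
        for ev, report in _exhaustive(plasmid, amplicon):
            got = report.classification == "in_frame_candidate"
            want = is_candidate(
                plasmid.sequence,
                orf.start,
                orf.end,
                strand,
                amplicon.sequence,
                marker,
                target_pep,
                ev.cut_bond,
                ev.orientation,
            )
            assert got == want, (ev.cut_bond, ev.orientation, report.classification)
            n_classifier += got
            n_oracle += want
        assert n_classifier == n_oracle > 0


class TestRuleAssignments:
    def test_backbone(self, toy_plasmid, toy_amplicon):
        orf = toy_plasmid.orfs[0]
        cut = (orf.end + 30) % len(toy_plasmid)
        ev = insert_at(toy_plasmid, toy_amplicon, cut, "forward")
        assert classify_event(ev, toy_plasmid, orf).classification == "backbone"

    @pytest.mark.parametrize("offset", [0, 1, 2])  # 9-mer touching the start codon
    def test_orf_edge_at_start(self, toy_plasmid, toy_amplicon, offset):
        orf = toy_plasmid.orfs[0]
        ev = insert_at(toy_plasmid, toy_amplicon, orf.start + offset, "forward")
        assert classify_event(ev, toy_plasmid, orf).classification == "orf_edge"

    def test_orf_edge_at_stop(self, toy_plasmid, toy_amplicon):
        orf = toy_plasmid.orfs[0]
        ev = insert_at(toy_plasmid, toy_amplicon, orf.end - 9, "forward")
        assert classify_event(ev, toy_plasmid, orf).classification == "orf_edge"

    def test_wrong_orientation(self, toy_plasmid, toy_amplicon):
        orf = toy_plasmid.orfs[0]
        ev = insert_at(toy_plasmid, toy_amplicon, orf.start + 30, "reverse")
        assert classify_event(ev, toy_plasmid, orf).classification == "wrong_orientation"

    @pytest.mark.parametrize("shift", [1, 2])
    def test_within_codon_cut_is_out_of_frame(self, toy_plasmid, toy_amplicon, shift):
        orf = toy_plasmid.orfs[0]
        ev = insert_at(toy_plasmid, toy_amplicon, orf.start + 30 + shift, "forward")
        assert classify_event(ev, toy_plasmid, orf).classification == "out_of_frame"

    def test_wrong_plasmid_rejected(self, toy_plasmid, toy_amplicon):
        other = fixtures.synth_plasmid(77, 150, 150, label="toy")
        ev = insert_at(toy_plasmid, toy_amplicon, 10, "forward")
        with pytest.raises(ConfigurationError):
            classify_event(ev, other, other.orfs[0])


@pytest.fixture(scope="module")
def report(toy_plasmid, toy_amplicon):
    orf = toy_plasmid.orfs[0]
    ev = insert_at(toy_plasmid, toy_amplicon, orf.start + 30, "forward")
    return classify_event(ev, toy_plasmid, orf), orf, toy_amplicon


class TestInFrameReports:

    def test_junction_bookkeeping(self, report, toy_plasmid):
        rep, orf, amp = report
        assert rep.classification == "in_frame_candidate"
        assert rep.codon_N == 10
        assert rep.codon_N3 == 13
        sense = toy_plasmid.orf_sense(orf)
        assert rep.duplicated_codons == translate(sense[30:39])

    def test_no_extra_linker_codon_counts(self, report):
        rep, _, _ = report
        assert len(rep.linker5_peptide) == 6  # spacer codons, 5' side
        assert len(rep.linker3_peptide) + len(rep.duplicated_codons) == 9

    def test_chimera_composition(self, report, toy_plasmid):
        rep, orf, amp = report
        n_sense = orf.codon_count(len(toy_plasmid)) - 1
        assert len(rep.chimera) == n_sense + 3 + len(amp) // 3
        assert "*" not in rep.chimera
        target_pep = translate(toy_plasmid.orf_sense(orf))[:-1]
        assert rep.chimera.startswith(target_pep[: rep.codon_N3])
        assert rep.chimera.endswith(target_pep[rep.codon_N :])

    def test_duplicated_tripeptide_appears_twice(self, toy_plasmid, toy_amplicon):
        orf = toy_plasmid.orfs[0]
        target_pep = translate(toy_plasmid.orf_sense(orf))[:-1]
        amp_pep = translate(toy_amplicon.sequence)
        checked = 0
        for k in range(1, orf.codon_count(len(toy_plasmid)) - 4):
            ev = insert_at(toy_plasmid, toy_amplicon, orf.start + 3 * k, "forward")
            rep = classify_event(ev, toy_plasmid, orf)
            assert rep.classification == "in_frame_candidate"
            dup = rep.duplicated_codons
            if target_pep.count(dup) == 1 and dup not in amp_pep:
                assert rep.chimera.count(dup) == 2
                checked += 1
        assert checked > 0


class TestMonotonicity:
    def test_in_frame_fraction_grows_with_orf_length(self):
        """At fixed plasmid size, a longer ORF never lowers the exact
        in-frame fraction (computed by exhausting every cut bond)."""
        total = 600
        fractions = []
        amp = design_amplicon(fixtures.synth_fp_orf(13, aa_len=20), "none")
        for orf_len in (60, 150, 240, 330, 420):
            plasmid = fixtures.synth_plasmid(31, total - orf_len, orf_len, label="t")
            orf = plasmid.orfs[0]
            hits = sum(
                classify_event(
                    insert_at(plasmid, amp, cut, "forward"), plasmid, orf
                ).classification
                == "in_frame_candidate"
                for cut in range(total)
            )
            fractions.append(hits / total)
        assert fractions == sorted(fractions)


class TestSummaries:
    def test_counts_and_histogram(self, toy_plasmid, toy_amplicon):
        events = simulate_library(toy_plasmid, toy_amplicon, 400, seed=3)
        reports = [classify_event(e, toy_plasmid, toy_plasmid.orfs[0]) for e in events]
        summary = summarize_library(reports)
        assert sum(summary.class_counts.values()) == 400
        in_frame_sites = {
            r.codon_N for r in reports if r.classification == "in_frame_candidate"
        }
        assert set(summary.site_histogram) == in_frame_sites
        assert sum(summary.site_histogram.values()) == summary.n_in_frame
        assert summary.ci_low <= summary.in_frame_fraction <= summary.ci_high

    def test_single_class_input(self, toy_plasmid, toy_amplicon):
        orf = toy_plasmid.orfs[0]
        cut = (orf.end + 20) % len(toy_plasmid)
        reports = [
            classify_event(insert_at(toy_plasmid, toy_amplicon, cut, "forward"), toy_plasmid, orf)
            for _ in range(5)
        ]
        summary = summarize_library(reports)
        assert summary.class_counts == {"backbone": 5}
        assert summary.site_histogram == {}

    def test_empty_input_warns(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            summary = summarize_library([])
        assert summary.n_events == 0
        assert caught
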