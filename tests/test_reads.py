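"""Read processing: demultiplexing, trim-rescue, fragment-end counting."""

import numpy as np
import pandas as pd
import pytest

from fourc.fragments import Enzyme
from fourc.reads import (AlignmentRecord, assemble_count_matrix, count_bam,
                         count_reads, demultiplex, qc_valid_fraction,
                         trim_to_second_site)
from fourc.simulate import simulate_alignments, write_bam

CATG = Enzyme("second", "CATG", 0)


@pytest.fixture()
def mini_fragments():
    """Two fragments on chr1; the first has second-cutter cuts at 130/170."""
    tab = pd.DataFrame(
        {
            "frag_id": [0, 1],
            "chrom": ["chr1", "chr1"],
            "start": [100, 200],
            "end": [200, 300],
            "midpoint": [150.0, 250.0],
            "has_second_site": [True, False],
            "left_cut": [130.0, np.nan],
            "right_cut": [170.0, np.nan],
            "left_end_length": [30.0, np.nan],
            "right_end_length": [30.0, np.nan],
            "left_end_valid": [True, False],
            "right_end_valid": [True, False],
            "is_valid": [True, False],
        }
    ).set_index("frag_id", drop=False).rename_axis(index=None)
    return tab


def _rec(start, end, strand):
    return AlignmentRecord("chr1", start, end, strand)


class TestCountingRules:
    def test_first_cutter_both_ends(self, mini_fragments):
        # left end: + read starting at the fragment start; right end: - read
        # whose 5' terminus is the fragment end; both point inward
        recs = [_rec(100, 130, "+"), _rec(170, 200, "-")]
        counts, qc = count_reads(recs, mini_fragments, "first_cutter_primer")
        assert counts.loc[0] == 2 and counts.loc[1] == 0
        assert qc["assigned_valid"] == 2

    def test_internal_start_rejected(self, mini_fragments):
        counts, qc = count_reads([_rec(150, 180, "+")], mini_fragments,
                                 "first_cutter_primer")
        assert counts.sum() == 0
        assert qc["rejected_not_at_cut_site"] == 1

    def test_wrong_strand_rejected(self, mini_fragments):
        # - read at the fragment start points outward under this protocol
        counts, _ = count_reads([_rec(70, 100, "-")], mini_fragments,
                                "first_cutter_primer")
        assert counts.sum() == 0

    def test_second_cutter_rules(self, mini_fragments):
        # reads anchor on the second-enzyme cut coordinates and point outward
        recs = [_rec(100, 130, "-"), _rec(170, 200, "+")]
        counts, _ = count_reads(recs, mini_fragments, "second_cutter_primer")
        assert counts.loc[0] == 2
        # the same coordinates with flipped strands must be rejected
        bad = [_rec(100, 130, "+"), _rec(170, 200, "-")]
        counts2, qc2 = count_reads(bad, mini_fragments, "second_cutter_primer")
        assert counts2.sum() == 0 and qc2["rejected_not_at_cut_site"] == 2

    def test_slack_window(self, mini_fragments):
        off = [_rec(101, 130, "+")]
        strict, _ = count_reads(off, mini_fragments, "first_cutter_primer", slack=0)
        loose, _ = count_reads(off, mini_fragments, "first_cutter_primer", slack=1)
        assert strict.sum() == 0 and loose.loc[0] == 1

    def test_invalid_fragment_counted_separately(self, mini_fragments):
        counts, qc = count_reads([_rec(200, 230, "+")], mini_fragments,
                                 "first_cutter_primer")
        assert counts.loc[1] == 1
        assert qc["assigned_invalid"] == 1 and qc["assigned_valid"] == 0
        mat = assemble_count_matrix({"s": counts}, mini_fragments, valid_only=True)
        assert 1 not in mat.index  # invalid fragments excluded downstream

    def test_unknown_chromosome_errors(self, mini_fragments):
        with pytest.raises(ValueError, match="chrX"):
            count_reads([AlignmentRecord("chrX", 0, 30, "+")], mini_fragments,
                        "first_cutter_primer")

    def test_low_mapq_rejected(self, mini_fragments):
        rec = AlignmentRecord("chr1", 100, 130, "+", mapq=3)
        counts, qc = count_reads([rec], mini_fragments, "first_cutter_primer",
                                 min_mapq=10)
        assert counts.sum() == 0 and qc["rejected_low_mapq"] == 1


class TestCountingProperties:
    def test_conservation_and_order_independence(self, toy_reference):
        _, frags, vp = toy_reference
        rng = np.random.default_rng(0)
        per_frag = pd.Series(rng.integers(0, 30, len(frags)), index=frags.index)
        recs, n_decoys = simulate_alignments(frags, per_frag, decoy_fraction=0.25,
                                             seed=1)
        counts, qc = count_reads(recs, frags, "first_cutter_primer")
        # decoys rejected exactly; every record accounted for
        assert qc["rejected_not_at_cut_site"] == n_decoys
        assert qc["total"] == len(recs)
        assert (qc["assigned_valid"] + qc["assigned_invalid"]
                + qc["rejected_not_at_cut_site"]) == qc["total"]
        assert counts.sum() == per_frag.sum()
        # shuffling the record order changes nothing
        rng.shuffle(recs)
        counts2, _ = count_reads(recs, frags, "first_cutter_primer")
        assert counts.equals(counts2)

    def test_exact_start_rule_shift_sensitivity(self, toy_reference):
        """With slack=0 a one-nt shift of every alignment voids all counts."""
        _, frags, _ = toy_reference
        per_frag = pd.Series(5, index=frags.index)
        recs, _ = simulate_alignments(frags, per_frag, seed=2)
        shifted = [AlignmentRecord(r.chrom, r.start + 1, r.end + 1, r.strand)
                   for r in recs]
        counts, _ = count_reads(shifted, frags, "first_cutter_primer")
        assert counts.sum() == 0

    def test_protocol_mismatch_rejects_everything(self, toy_reference):
        _, frags, _ = toy_reference
        per_frag = pd.Series(3, index=frags.index)
        recs, _ = simulate_alignments(frags, per_frag,
                                      protocol="first_cutter_primer", seed=3)
        counts, _ = count_reads(recs, frags, "second_cutter_primer")
        assert counts.sum() == 0

    def test_bam_round_trip(self, toy_reference, tmp_path):
        _, frags, _ = toy_reference
        rng = np.random.default_rng(4)
        per_frag = pd.Series(rng.integers(0, 20, len(frags)), index=frags.index)
        recs, _ = simulate_alignments(frags, per_frag, seed=4)
        path = tmp_path / "toy.bam"
        write_bam(recs, frags, path)
        counts, qc = count_bam(path, frags, "first_cutter_primer")
        assert counts.equals(per_frag)
        assert qc["total"] == len(recs)


class TestQC:
    def test_valid_fraction_arithmetic(self):
        qc = {"total": 100, "assigned_valid": 90}
        assert qc_valid_fraction(qc) == pytest.approx(0.90)

    def test_zero_assigned_warns(self):
        with pytest.warns(UserWarning, match="valid fragments"):
            frac = qc_valid_fraction({"total": 50, "assigned_valid": 0})
        assert frac == 0.0

    def test_conforming_simulation_hits_one(self, toy_reference):
        _, frags, _ = toy_reference
        per_frag = pd.Series(4, index=frags.index)
        recs, _ = simulate_alignments(frags, per_frag, seed=5)
        _, qc = count_reads(recs, frags, "first_cutter_primer")
        assert qc_valid_fraction(qc) == pytest.approx(1.0)


class TestDemultiplex:
    def _records(self, seqs):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        return [
            SeqRecord(Seq(s), id=f"r{i}",
                      letter_annotations={"phred_quality": [30] * len(s)})
            for i, s in enumerate(seqs)
        ]

    PRIMERS = {"vp1": "ACGTACGTAC", "vp2": "TTGGCCAATT"}

    def test_exact_prefix_assignment_and_trim(self):
        recs = self._records(["ACGTACGTACGGGG", "TTGGCCAATTCCCC", "AAAAAAAAAAAAAA"])
        out = list(demultiplex(recs, self.PRIMERS))
        assert [name for name, _ in out] == ["vp1", "vp2", None]
        assert str(out[0][1].seq) == "GGGG"
        assert str(out[1][1].seq) == "CCCC"

    def test_one_mismatch_tolerated(self):
        recs = self._records(["ACGAACGTACGGGG"])  # one mismatch in vp1 primer
        (name, rec), = demultiplex(recs, self.PRIMERS, max_mismatch=1)
        assert name == "vp1" and str(rec.seq) == "GGGG"

    def test_prefix_conflict_rejected(self):
        with pytest.raises(ValueError, match="prefix"):
            list(demultiplex(self._records(["AAAA"]),
                             {"a": "ACGT", "b": "ACGTAC"}))


class TestTrimRescue:
    def test_truncation_at_cut_site(self):
        assert trim_to_second_site("AAAATTTTCATGGGGG", CATG) == "AAAATTTT"

    def test_no_site_unchanged(self):
        assert trim_to_second_site("AAAATTTTGGGG", CATG) == "AAAATTTTGGGG"

    def test_leading_site_dropped(self):
        assert trim_to_second_site("CATGAAAA", CATG) is None

    def test_cut_offset_respected(self):
        enz = Enzyme("e", "CATG", 2)
        assert trim_to_second_site("AAAACATGTTTT", enz) == "AAAACA"
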