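import numpy as np
import pytest

from schoco.formats import SequenceRecord, reverse_complement
from schoco.guide_screen import (
    PRIMERS,
    SELECTED_SPACER,
    SCAFFOLD_PREFIX,
    SPECIFIC_OLIGO,
    T7_PROMOTER,
    UNIVERSAL_OLIGO,
    SpacerError,
    assemble_sgrna_template,
    conservation_coverage,
    enumerate_candidates,
    extract_spacer,
    find_target_sites,
    joint_coverage,
    offtarget_screen,
    primer_sites,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):  # independent of the package helper
    return "".join(COMP[b] for b in reversed(s))


def brute_force_sites(spacer, seq, max_mm, require_pam):
    """Naive oracle: enumerate every 20-mer on both strands."""
    hits = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - 19):
            mm = sum(a != b for a, b in zip(spacer, s[i: i + 20]))
            if mm > max_mm:
                continue
            if require_pam:
                pam = s[i + 20: i + 23]
                if len(pam) < 3 or pam[1:] != "GG":
                    continue
            hits.append((i, strand, mm))
    return sorted(hits)


class TestExtractSpacer:
    def test_printed_oligo_decomposes_into_three_segments(self):
        spacer = extract_spacer(SPECIFIC_OLIGO)
        assert spacer == SELECTED_SPACER
        assert len(spacer) == 20
        # promoter + initiating G + spacer + scaffold re-concatenate exactly
        assert T7_PROMOTER + "G" + spacer + SCAFFOLD_PREFIX == SPECIFIC_OLIGO

    def test_missing_promoter_anchor(self):
        with pytest.raises(SpacerError, match="promoter"):
            extract_spacer(SPECIFIC_OLIGO[len(T7_PROMOTER):])

    def test_wrong_insert_length(self):
        bad = T7_PROMOTER + "ACGTACGTACGTACGTACG" + SCAFFOLD_PREFIX
        with pytest.raises(SpacerError, match="19"):
            extract_spacer(bad)


class TestEnumerateCandidates:
    def test_single_plus_strand_site(self):
        spacer = "ATCGATCGATCGATCGATCG"
        rec = SequenceRecord("r", "", "TTTT" + spacer + "AGG" + "TTT")
        cands = enumerate_candidates(rec)
        assert len(cands) == 1
        c = cands[0]
        assert (c.spacer, c.pam, c.strand, c.start) == (spacer, "AGG", "+", 4)

    def test_no_gg_or_cc_dinucleotide_means_no_candidates(self):
        rec = SequenceRecord("r", "", "AGAGAGAGATCTCTCTCTATATAGAGATAT" * 2)
        assert enumerate_candidates(rec) == []

    def test_minus_strand_candidate_is_reverse_complement_context(self):
        spacer = "ATCGATCGATCGATCGATCG"
        plus = "TTTT" + "CCT" + revcomp(spacer) + "TTTT"
        rec = SequenceRecord("r", "", plus)
        cands = enumerate_candidates(rec)
        minus = [c for c in cands if c.strand == "-"]
        assert len(minus) == 1
        assert minus[0].spacer == spacer
        assert minus[0].pam == "AGG"

    def test_window_outside_sequence_errors(self):
        rec = SequenceRecord("r", "", "ACGT" * 10)
        with pytest.raises(ValueError):
            enumerate_candidates(rec, 0, 100)


class TestFindTargetSites:
    def test_embedded_exact_site(self, rng):
        seq = ("".join(rng.choice(list("ACGT"), 10)) + SELECTED_SPACER
               + "AGG" + "".join(rng.choice(list("ACGT"), 10)))
        hits = find_target_sites(SELECTED_SPACER,
                                 [SequenceRecord("r", "", seq)], 0, True)
        assert len(hits) == 1 and hits[0].mismatches == 0

    def test_bad_pam_rejected_when_required(self):
        seq = "T" * 10 + SELECTED_SPACER + "ATT" + "T" * 10
        rec = SequenceRecord("r", "", seq)
        assert find_target_sites(SELECTED_SPACER, [rec], 0, True) == []
        assert len(find_target_sites(SELECTED_SPACER, [rec], 0, False)) == 1

    def test_non_acgt_spacer_rejected(self):
        with pytest.raises(SpacerError):
            find_target_sites("N" * 20, [], 0)

    def test_matches_brute_force_oracle_on_random_db(self, rng):
        spacer = "".join(rng.choice(list("ACGT"), 20))
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 300))
            for require_pam in (True, False):
                got = find_target_sites(
                    spacer, [SequenceRecord("r", "", seq)], 2, require_pam
                )
                assert (
                    sorted((h.position, h.strand, h.mismatches) for h in got)
                    == brute_force_sites(spacer, seq, 2, require_pam)
                )

    def test_strand_symmetry(self, rng, toy_refdb):
        flipped = [
            SequenceRecord(r.id, r.description,
                           reverse_complement(r.seq), r.lineage)
            for r in toy_refdb
        ]
        fwd = find_target_sites(SELECTED_SPACER, toy_refdb, 2, True)
        rev = find_target_sites(SELECTED_SPACER, flipped, 2, True)
        flip = {"+": "-", "-": "+"}
        assert sorted((h.seq_id, h.position, flip[h.strand], h.mismatches)
                      for h in fwd) == sorted(
            (h.seq_id, h.position, h.strand, h.mismatches) for h in rev
        )

    def test_hits_monotone_in_mismatch_budget(self, toy_refdb):
        prev = set()
        for k in range(4):
            cur = {
                (h.seq_id, h.position, h.strand)
                for h in find_target_sites(SELECTED_SPACER, toy_refdb, k, True)
            }
            assert prev <= cur
            prev = cur


class TestCoverage:
    def _db(self, with_site, without_site):
        recs = []
        for i in range(with_site):
            recs.append(SequenceRecord(
                f"hit{i}", f"hit{i}.1.1 Bacteria;P;C;O;FamA;G",
                "ACGT" * 5 + SELECTED_SPACER + "TGG" + "ACGT" * 5,
                lineage=None))
        for i in range(without_site):
            recs.append(SequenceRecord(
                f"miss{i}", f"miss{i}.1.1 Bacteria;P;C;O;FamB;G",
                "ACGTACGTAT" * 8, lineage=None))
        from schoco.formats import parse_taxonomy_header
        for r in recs:
            r.lineage = parse_taxonomy_header(r.description, "silva")
        return recs

    def test_three_of_four_covered(self):
        rep = conservation_coverage(SELECTED_SPACER, self._db(3, 1))
        assert rep.n_hit == 3 and rep.fraction == 0.75
        assert rep.miss_ids == ["miss0"]

    def test_full_coverage(self):
        rep = conservation_coverage(SELECTED_SPACER, self._db(4, 0))
        assert rep.fraction == 1.0 and rep.miss_ids == []

    def test_per_taxon_buckets_sum_to_totals(self):
        rep = conservation_coverage(SELECTED_SPACER, self._db(3, 2),
                                    rank="family")
        assert sum(nd for nd, _ in rep.per_taxon.values()) == rep.n_db
        assert sum(nh for _, nh in rep.per_taxon.values()) == rep.n_hit

    def test_fraction_invariant_to_db_order(self):
        db = self._db(3, 2)
        rep1 = conservation_coverage(SELECTED_SPACER, db)
        rep2 = conservation_coverage(SELECTED_SPACER, db[::-1])
        assert rep1.fraction == rep2.fraction

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            conservation_coverage(SELECTED_SPACER, [])


class TestOfftargetScreen:
    def test_partition_of_planted_decoys(self, toy_refdb):
        decoys = toy_refdb[1:]  # prokaryote database analogue
        rep = offtarget_screen(SELECTED_SPACER, decoys, max_mm=2)
        assert rep.counts_by_mismatch() == {0: 0, 1: 1, 2: 1}
        # the PAM-less exact protospacer is never a hit
        assert all(h.seq_id != "dec_nopam"
                   for h in rep.exact_hits + rep.excluded_hits)
        # the chloroplast-annotated exact site lands in excluded only
        assert {h.seq_id for h in rep.excluded_hits} == {"dec_chloro"}
        assert rep.fraction_flagged == pytest.approx(2 / len(decoys))

    def test_three_mismatch_decoy_not_found_at_two(self, toy_refdb):
        rep = offtarget_screen(SELECTED_SPACER, toy_refdb[1:], max_mm=2)
        assert all(h.seq_id != "dec_mm3"
                   for hits in rep.near_hits.values() for h in hits)
        rep3 = offtarget_screen(SELECTED_SPACER, toy_refdb[1:], max_mm=3)
        assert any(h.seq_id == "dec_mm3" for h in rep3.near_hits[3])


class TestPrimerSites:
    def test_515f_degenerate_match(self):
        rec = SequenceRecord("r", "", "TT" + "GTGCCAGCAGCCGCGGTAA" + "TT")
        assert primer_sites(PRIMERS["515F"], rec) == [(2, "+")]

    def test_515f_nonmatching_expansion(self):
        rec = SequenceRecord("r", "", "TT" + "GTGCCAGCTGCCGCGGTAA" + "TT")
        assert primer_sites(PRIMERS["515F"], rec) == []

    def test_reverse_primer_found_on_minus_strand(self, rng):
        expansion = "".join(
            rng.choice(sorted({"A": "A", "C": "C", "G": "G", "T": "T",
                               "H": "ACT", "V": "ACG", "W": "AT",
                               "Y": "CT", "M": "AC"}[b]))
            for b in PRIMERS["806R"]
        )
        rec = SequenceRecord("r", "", "CAAT" + revcomp(expansion) + "GGTC")
        assert (4, "-") in primer_sites(PRIMERS["806R"], rec)


class TestJointCoverage:
    def test_constructed_positive(self, toy_chloroplast):
        rep = joint_coverage(SELECTED_SPACER, [toy_chloroplast])
        assert rep.n_hit == 1

    def test_truncation_before_outer_reverse_site_uncovers(self, toy_chloroplast):
        truncated = SequenceRecord(
            "t", toy_chloroplast.description,
            toy_chloroplast.seq[: len(toy_chloroplast.seq) - 60],
            toy_chloroplast.lineage,
        )
        assert joint_coverage(SELECTED_SPACER, [truncated]).n_hit == 0

    def test_decoys_not_covered(self, toy_refdb):
        rep = joint_coverage(SELECTED_SPACER, toy_refdb)
        assert rep.n_hit == 1
        assert set(rep.miss_ids) == {r.id for r in toy_refdb[1:]}

    def test_antisense_record_still_covered(self, toy_chloroplast):
        flipped = SequenceRecord(
            "f", toy_chloroplast.description,
            reverse_complement(toy_chloroplast.seq), toy_chloroplast.lineage,
        )
        assert joint_coverage(SELECTED_SPACER, [flipped]).n_hit == 1

    def test_spacer_site_lies_inside_v4_window(self, toy_chloroplast):
        """The guide cuts between the inner primer sites (central V4)."""
        f515 = [p for p, s in primer_sites(PRIMERS["515F"], toy_chloroplast)
                if s == "+"]
        r806 = [p for p, s in primer_sites(PRIMERS["806R"], toy_chloroplast)
                if s == "-"]
        hit = find_target_sites(SELECTED_SPACER, [toy_chloroplast], 0, True)[0]
        assert hit.strand == "+"
        assert f515[0] + len(PRIMERS["515F"]) < hit.position
        assert hit.position + 23 <= r806[0]


class TestSgrnaTemplateAssembly:
    def test_printed_oligos_fuse_with_8nt_linker(self):
        # independent oracle: brute-force longest suffix/prefix overlap
        univ_rc = revcomp(UNIVERSAL_OLIGO)
        best = max(
            k for k in range(1, len(SPECIFIC_OLIGO) + 1)
            if SPECIFIC_OLIGO[-k:] == univ_rc[:k]
        )
        assert best == 8
        tpl = assemble_sgrna_template(UNIVERSAL_OLIGO, SPECIFIC_OLIGO)
        assert tpl.overlap == 8
        assert tpl.length == 121
        assert tpl.seq == SPECIFIC_OLIGO + univ_rc[8:]

    def test_total_overlap(self):
        spec = "ACGTACGTACGT"
        tpl = assemble_sgrna_template(revcomp(spec), spec)
        assert tpl.length == len(spec)

    def test_no_linker_errors(self):
        with pytest.raises(SpacerError, match="no linker"):
            assemble_sgrna_template("CCCCCCCCCC", "AAAAAAAAAA")
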