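"""Duplicate collapse, mature/star designation, miRNA enumeration, the
known/novel decision tree, and structural validation."""

import math
import types

import numpy as np
import pytest

from crossmir import precursor_annotation as ann
from crossmir import synthetic_data as syn


def make_precursor(pid, start=1000, end=None, strand="+", mature_count=100,
                   star_count=10, dataset="ds1", seed=0, reference="chr1"):
    tp = syn.generate_precursor(21, 20, (18, 18), seed=seed)
    end = end if end is not None else start + len(tp.sequence)
    return ann.MiRNAPrecursor(pid, reference, start, end, strand, tp.sequence,
                              tp.mature, tp.star, mature_count, star_count,
                              dataset, tp.dot_bracket)


class TestCollapseDuplicates:
    def test_highest_mature_count_retained(self):
        a = make_precursor("a", mature_count=100)
        b = make_precursor("b", mature_count=40, dataset="ds2")
        retained, groups = ann.collapse_duplicates([a, b])
        assert [p.id for p in retained] == ["a"]
        assert groups["a"] == ["a", "b"]

    def test_opposite_strands_both_retained(self):
        a = make_precursor("a", strand="+")
        b = make_precursor("b", strand="-")
        retained, _ = ann.collapse_duplicates([a, b])
        assert len(retained) == 2

    def test_tie_prefers_smallest_dataset_id(self, caplog):
        a = make_precursor("a", mature_count=50, dataset="ds2")
        b = make_precursor("b", mature_count=50, dataset="ds1")
        with caplog.at_level("WARNING"):
            retained, _ = ann.collapse_duplicates([a, b])
        assert [p.id for p in retained] == ["b"]
        assert "tie" in caplog.text

    def test_below_threshold_overlap_not_collapsed(self):
        a = make_precursor("a", start=1000)           # ~98 nt locus
        b = make_precursor("b", start=1060)           # < 50% reciprocal overlap
        retained, _ = ann.collapse_duplicates([a, b])
        assert len(retained) == 2

    def test_random_groups_match_component_argmax_oracle(self, rng):
        """Brute-force oracle: connected components via networkx over the
        pairwise overlap predicate, argmax mature count per component."""
        import networkx as nx

        precursors = []
        pos = 0
        for i in range(40):
            pos += int(rng.integers(0, 120))
            precursors.append(make_precursor(
                f"p{i:02d}", start=pos, mature_count=int(rng.integers(1, 1000)),
                strand="+" if rng.random() < 0.8 else "-",
                dataset=f"ds{int(rng.integers(1, 4))}"))
        retained, groups = ann.collapse_duplicates(precursors)

        g = nx.Graph()
        g.add_nodes_from(range(len(precursors)))
        for i in range(len(precursors)):
            for j in range(i + 1, len(precursors)):
                a, b = precursors[i], precursors[j]
                ov = min(a.end, b.end) - max(a.start, b.start)
                if (a.strand == b.strand and ov > 0
                        and ov >= 0.5 * (a.end - a.start)
                        and ov >= 0.5 * (b.end - b.start)):
                    g.add_edge(i, j)
        expected = set()
        for comp in nx.connected_components(g):
            members = [precursors[i] for i in comp]
            best = max(members, key=lambda p: (p.mature_count, ),)
            ties = [p for p in members if p.mature_count == best.mature_count]
            expected.add(min(ties, key=lambda p: p.dataset_id).id)
        assert {p.id for p in retained} == expected
        assert sum(len(v) for v in groups.values()) == len(precursors)


class TestMatureStar:
    @pytest.mark.parametrize("counts,expected", [
        ((370, 12), "first"), ((0, 5), "second"), ((5, 0), "first")])
    def test_higher_count_is_mature(self, counts, expected):
        arm, warned = ann.assign_mature_star(*counts)
        assert arm == expected and not warned

    def test_tie_designates_first_arm_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            arm, warned = ann.assign_mature_star(7, 7)
        assert arm == "first" and warned and "tie" in caplog.text.lower()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ann.assign_mature_star(-1, 0)


class TestEnumerate:
    def test_duplicated_precursors_share_mirnas(self):
        a = make_precursor("a", seed=7)
        b = make_precursor("b", start=5000, end=5000 + len(a.sequence), seed=7)
        mirnas = ann.enumerate_mirnas([a, b])
        assert len(mirnas) == 2
        for m in mirnas:
            assert m.precursor_ids == ["a", "b"]

    def test_distinct_arms_two_mirnas(self):
        mirnas = ann.enumerate_mirnas([make_precursor("a")])
        assert len(mirnas) == 2
        assert mirnas[0].sequence != mirnas[1].sequence

    def test_unique_count_matches_set_oracle(self, rng):
        precs = [make_precursor(f"p{i}", start=1000 * i,
                                seed=int(rng.integers(0, 5)))
                 for i in range(20)]
        mirnas = ann.enumerate_mirnas(precs)
        oracle = {p.mature_sequence for p in precs} | {p.star_sequence for p in precs}
        assert len(mirnas) == len(oracle)
        assert len(mirnas) <= 2 * len(precs)
        for m in mirnas:
            for pid in m.precursor_ids:
                p = next(x for x in precs if x.id == pid)
                assert m.sequence in (p.mature_sequence, p.star_sequence)

    def test_collapse_then_enumerate_is_idempotent_and_shrinking(self, rng):
        precs = [make_precursor(f"p{i}", start=int(rng.integers(0, 500)),
                                mature_count=int(rng.integers(1, 100)),
                                seed=int(rng.integers(0, 3)))
                 for i in range(15)]
        collapsed, _ = ann.collapse_duplicates(precs)
        again, _ = ann.collapse_duplicates(collapsed)
        assert {p.id for p in again} == {p.id for p in collapsed}
        assert len(ann.enumerate_mirnas(collapsed)) <= len(ann.enumerate_mirnas(precs))


EV = ann.ClassificationEvidence


class TestClassify:
    @pytest.mark.parametrize("evidence,expected", [
        (EV(1e-12), "known"),                        # strong precursor homology
        (EV(1e-5, 0.72), "known"),                   # middle tier, high coverage
        (EV(1e-5, 0.40, (1e-8,)), "novel"),          # weak arm-level evidence
        (EV(1e-2), "novel"),                         # no meaningful homology
        (EV(1e-5, 0.40, (1e-12, 0.5)), "known"),     # one strong arm suffices
    ])
    def test_documented_examples(self, evidence, expected):
        assert ann.classify_precursor(evidence).status == expected

    def test_boundary_semantics(self):
        # e exactly 1e-10 falls in the middle tier (not known outright)
        assert ann.classify_precursor(EV(1e-10, 0.72)).status == "known"
        assert ann.classify_precursor(EV(1e-10, 0.40, (1e-9,))).status == "novel"
        # coverage exactly 0.60 -> known
        assert ann.classify_precursor(EV(1e-5, 0.60)).status == "known"
        assert ann.classify_precursor(EV(1e-5, 0.599999, (1,))).status == "novel"
        # short e exactly 1e-10 -> novel
        assert ann.classify_precursor(EV(1e-5, 0.40, (1e-10,))).status == "novel"
        # e exactly 1e-3 -> novel outright
        assert ann.classify_precursor(EV(1e-3)).status == "novel"

    def test_missing_short_evidence_is_unset(self):
        c = ann.classify_precursor(EV(1e-5, 0.40))
        assert c.status == "unset" and "short" in c.note

    def test_missing_coverage_is_unset(self):
        assert ann.classify_precursor(EV(1e-5)).status == "unset"

    def test_total_over_exhaustive_grid(self):
        """Every combination classifies; middle tier only consults coverage."""
        for e in (0.0, 1e-12, 1e-10, 1e-6, 1e-3, 1.0, 10.0):
            for cov in (None, 0.0, 0.59, 0.60, 0.61, 1.0):
                for short in ((), (1e-11,), (1e-10,), (1e-9,)):
                    c = ann.classify_precursor(EV(e, cov, short))
                    assert c.status in ("known", "novel", "unset")
                    if e < 1e-10:
                        assert c.status == "known"
                    elif e >= 1e-3:
                        assert c.status == "novel"


class TestEvidenceAssembly:
    def test_best_hit_and_arm_evalues_collected(self):
        from crossmir.smallrna_io import HomologyRecord
        prec = make_precursor("p1")
        records = [
            HomologyRecord("p1", "mir1", 1e-4, 0.5, "precursor_blast"),
            HomologyRecord("p1", "mir2", 1e-6, 0.4, "precursor_blast"),
            HomologyRecord("p1.mature", "mir1", 1e-12, 0.9, "short_blast"),
            HomologyRecord("p1.star", "mir1", 1e-2, 0.9, "short_blast"),
            HomologyRecord("other", "mir1", 1e-20, 0.9, "precursor_blast"),
        ]
        ev = ann.evidence_from_homology(prec, records)
        assert ev.precursor_evalue == 1e-6 and ev.precursor_coverage == 0.4
        assert set(ev.short_evalues) == {1e-12, 1e-2}
        assert ann.classify_precursor(ev).status == "known"

    def test_no_hits_classify_novel(self):
        prec = make_precursor("p1")
        ev = ann.evidence_from_homology(prec, [])
        assert ann.classify_precursor(ev).status == "novel"


class TestValidate:
    def test_perfect_hairpin_passes(self, hairpin):
        prec = make_precursor("p1")
        ok, reasons = ann.validate_precursor(prec, prec.dot_bracket)
        assert ok and reasons == []

    def test_overlong_precursor_fails_with_length_reason(self):
        fake = types.SimpleNamespace(sequence="A" * 301, mature=(18, 39),
                                     star=(262, 283))
        ok, reasons = ann.validate_precursor(fake, "." * 301)
        assert not ok and "length" in reasons

    def test_pairing_fraction_matches_pair_table_walk(self, rng):
        """Oracle: an independent stack walk over the dot-bracket string."""
        for seed in range(5):
            tp = syn.generate_precursor(22, 18, (17, 17),
                                        n_mismatches=int(rng.integers(0, 6)),
                                        seed=seed)
            prec = ann.MiRNAPrecursor("p", "c", 0, len(tp.sequence), "+",
                                      tp.sequence, tp.mature, tp.star, 10, 1)
            stack, partner = [], {}
            for i, ch in enumerate(tp.dot_bracket):
                if ch == "(":
                    stack.append(i)
                elif ch == ")":
                    j = stack.pop()
                    partner[i], partner[j] = j, i
            m0, m1 = prec.mature
            s0, s1 = prec.star
            expected = sum(1 for i in range(m0, m1)
                           if i in partner and s0 <= partner[i] < s1) / (m1 - m0)
            assert math.isclose(
                ann.duplex_pairing_fraction(prec, tp.dot_bracket), expected)

    def test_low_pairing_fails(self):
        prec = make_precursor("p1")
        ok, reasons = ann.validate_precursor(prec, "." * len(prec.sequence))
        assert not ok and "duplex_pairing" in reasons

    def test_unbalanced_dot_bracket_rejected(self, hairpin):
        with pytest.raises(ValueError, match="unbalanced"):
            ann.pair_table("((..)")
        prec = make_precursor("p1")
        with pytest.raises(ValueError, match="length"):
            ann.validate_precursor(prec, "...")


class TestRoundTrips:
    def test_precursor_fasta_round_trip(self, tmp_path):
        precs = [make_precursor("a"), make_precursor("b", start=9000, strand="-",
                                                     mature_count=7, star_count=3)]
        path = tmp_path / "precs.fa"
        ann.write_precursor_fasta(precs, path)
        back = ann.read_precursor_fasta(path)
        for orig, rt in zip(precs, back):
            assert (rt.id, rt.sequence, rt.mature, rt.star, rt.strand,
                    rt.mature_count, rt.star_count, rt.start, rt.end) == \
                   (orig.id, orig.sequence, orig.mature, orig.star, orig.strand,
                    orig.mature_count, orig.star_count, orig.start, orig.end)

    def test_shortstack_dialect_table(self, tmp_path):
        prec = make_precursor("hp1", start=99)
        table = tmp_path / "results.txt"
        table.write_text(
            "Locus\tStrand\tName\tMajorRNA\tStar\tMajorRNAReads\tStarReads\n"
            f"chr1:100-{prec.end}\t+\thp1\t{prec.mature_sequence}\t"
            f"{prec.star_sequence}\t120\t8\n")
        out = ann.read_precursor_table(table, {"hp1": prec.sequence}, "dsX")
        assert out[0].mature == prec.mature and out[0].star == prec.star
        assert out[0].start == 99 and out[0].mature_count == 120
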