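import itertools

import numpy as np
import pandas as pd
import pytest

from loxkit.genome_model import LUArrangement, render
from loxkit.insilico_pcr import GenotypeMatrix, genotype
from loxkit.genotype_interpret import (DUPLICATION_CAVEAT, classify_pattern,
                                       compare_arrangements, diversity_score,
                                       insilico_crosscheck, select_candidates)
from loxkit.scramble_sim import RecombinationEvent, apply_event

JUNCTIONS_8 = [f"[{k}:{k+1}]" for k in range(8)]


def _row(missing, n=8):
    return [0 if k in missing else 1 for k in range(n)]


class TestClassifyPattern:
    def test_two_consecutive_missing_is_deletion_of_inner_lu(self):
        rep = classify_pattern(_row({1, 2}), JUNCTIONS_8)
        assert len(rep.candidates) == 1
        cand = rep.candidates[0]
        assert cand["kind_hypothesis"] == "deletion"
        assert cand["inferred_lu_span"] == ["LU2"]
        assert rep.n_missing == 2

    def test_all_present_reports_none_with_duplication_caveat(self):
        rep = classify_pattern([1] * 8, JUNCTIONS_8)
        assert [c["kind_hypothesis"] for c in rep.candidates] == ["none"]
        assert rep.candidates[0]["confidence_note"] == DUPLICATION_CAVEAT

    def test_two_distant_singletons_is_inversion_or_translocation(self):
        rep = classify_pattern(_row({1, 6}), JUNCTIONS_8)
        assert len(rep.candidates) == 1
        cand = rep.candidates[0]
        assert cand["kind_hypothesis"] == "inversion_or_translocation"
        assert cand["inferred_lu_span"] == [f"LU{k}" for k in range(2, 7)]

    def test_long_run_deletion_span(self):
        rep = classify_pattern(_row({2, 3, 4, 5}), JUNCTIONS_8)
        cand = rep.candidates[0]
        assert cand["kind_hypothesis"] == "deletion"
        assert cand["inferred_lu_span"] == ["LU3", "LU4", "LU5"]

    def test_lone_singleton_is_indeterminate(self):
        rep = classify_pattern(_row({3}), JUNCTIONS_8)
        assert [c["kind_hypothesis"] for c in rep.candidates] == ["indeterminate"]

    def test_three_singletons_all_indeterminate(self):
        rep = classify_pattern(_row({0, 3, 6}), JUNCTIONS_8)
        assert [c["kind_hypothesis"] for c in rep.candidates] == ["indeterminate"] * 3

    def test_mixed_run_and_singleton_pair(self):
        # one deletion run plus two singletons: both called, deletion ranked first
        rep = classify_pattern(_row({1, 2, 3, 5, 7}), JUNCTIONS_8)
        kinds = [c["kind_hypothesis"] for c in rep.candidates]
        assert kinds[0] == "deletion"
        assert "inversion_or_translocation" in kinds

    def test_candidates_cover_every_missing_junction_once(self):
        rep = classify_pattern(_row({0, 1, 4, 6}), JUNCTIONS_8)
        covered = [j for c in rep.candidates for j in c["junction_run"]]
        assert sorted(covered) == sorted(JUNCTIONS_8[k] for k in (0, 1, 4, 6))

    def test_circular_wrapping_run(self):
        # junctions 7 and 0 missing on a circular panel: one wrapped run of 2
        ids = [f"[{k}:{(k + 1) % 8}]" for k in range(8)]
        rep = classify_pattern(_row({0, 7}), ids, topology="circular")
        assert len(rep.candidates) == 1
        assert rep.candidates[0]["kind_hypothesis"] == "deletion"
        assert rep.candidates[0]["inferred_lu_span"] == ["LU0"]

    def test_circular_distant_pair_reports_shorter_arc(self):
        ids = [f"[{k}:{(k + 1) % 8}]" for k in range(8)]
        rep = classify_pattern(_row({0, 6}), ids, topology="circular")
        cand = rep.candidates[0]
        assert cand["kind_hypothesis"] == "inversion_or_translocation"
        assert cand["inferred_lu_span"] == ["LU7", "LU0"]
        assert "complementary arc" in cand["confidence_note"]

    def test_never_reports_duplication(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            row = rng.integers(0, 2, size=8).tolist()
            rep = classify_pattern(row, JUNCTIONS_8)
            assert all(c["kind_hypothesis"] != "duplication" for c in rep.candidates)

    def test_row_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="panel size"):
            classify_pattern([1, 0], JUNCTIONS_8)


def _arr(units, topology="linear"):
    return LUArrangement(topology, units, "ref")


REF4 = ["LU0", "LU1", "LU2", "LU3"]


class TestCompareArrangements:
    def test_single_inversion(self):
        obs = _arr([("LU0", "+"), ("LU2", "-"), ("LU1", "-"), ("LU3", "+")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts == {"deletions": 0, "inversions": 1, "complex": 0}
        assert comp.events == [{"kind": "inversion", "lu_ids": ["LU1", "LU2"]}]
        assert comp.breakpoints == 2

    def test_single_deletion(self):
        obs = _arr([("LU0", "+"), ("LU2", "+"), ("LU3", "+")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts == {"deletions": 1, "inversions": 0, "complex": 0}
        assert comp.events[0]["lu_ids"] == ["LU1"]

    def test_tandem_duplication_is_complex(self):
        obs = _arr([("LU0", "+"), ("LU1", "+"), ("LU1", "+"), ("LU2", "+"), ("LU3", "+")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts == {"deletions": 0, "inversions": 0, "complex": 1}
        assert comp.events[0]["kind"] == "duplication"

    def test_translocation_is_complex(self):
        ref5 = ["LU0", "LU1", "LU2", "LU3", "LU4"]
        obs = _arr([("LU0", "+"), ("LU2", "+"), ("LU3", "+"), ("LU1", "+"), ("LU4", "+")])
        comp = compare_arrangements(ref5, obs)
        assert comp.counts == {"deletions": 0, "inversions": 0, "complex": 1}
        assert comp.events == [{"kind": "translocation", "lu_ids": ["LU1"], "orientation": "+"}]

    def test_identity_has_no_events_or_breakpoints(self):
        comp = compare_arrangements(REF4, _arr([(lu, "+") for lu in REF4]))
        assert comp.counts == {"deletions": 0, "inversions": 0, "complex": 0}
        assert comp.breakpoints == 0

    def test_terminal_inversion(self):
        obs = _arr([("LU1", "-"), ("LU0", "-"), ("LU2", "+"), ("LU3", "+")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts == {"deletions": 0, "inversions": 1, "complex": 0}

    def test_multi_lu_deletion_single_event(self):
        obs = _arr([("LU0", "+"), ("LU3", "+")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts["deletions"] == 1
        assert comp.events[0]["lu_ids"] == ["LU1", "LU2"]

    def test_two_separate_deletions(self):
        ref6 = [f"LU{k}" for k in range(6)]
        obs = _arr([("LU0", "+"), ("LU2", "+"), ("LU3", "+"), ("LU5", "+")])
        comp = compare_arrangements(ref6, obs)
        assert comp.counts["deletions"] == 2

    def test_inverted_duplication_counts_once(self):
        obs = _arr([("LU0", "+"), ("LU1", "+"), ("LU2", "+"), ("LU3", "+"), ("LU1", "-")])
        comp = compare_arrangements(REF4, obs)
        assert comp.counts == {"deletions": 0, "inversions": 0, "complex": 1}

    def test_unknown_lu_rejected(self):
        with pytest.raises(ValueError, match="unknown LU"):
            compare_arrangements(REF4, _arr([("LU9", "+")]))

    def test_deletion_multiset_conservation_property(self, std_chrom, identity):
        from collections import Counter
        rng = np.random.default_rng(7)
        ref_ids = [lu.id for lu in std_chrom.lus]
        for seed in range(15):
            r = np.random.default_rng(seed)
            arr = identity
            for _ in range(int(r.integers(1, 4))):
                i = int(r.integers(0, len(arr) - 1))
                j = min(len(arr) - 1, i + int(r.integers(0, 2)))
                kind = ["deletion", "inversion", "duplication"][int(r.integers(0, 3))]
                try:
                    arr = apply_event(arr, RecombinationEvent(kind, (i, j)))
                except Exception:
                    continue
            comp = compare_arrangements(ref_ids, arr)
            reported = Counter()
            for ev in comp.events:
                if ev["kind"] == "deletion":
                    reported.update(ev["lu_ids"])
            truly_missing = Counter(ref_ids) - Counter(lu for lu, _ in arr.units)
            assert reported == +truly_missing

    def test_single_event_exactness_all_kinds_and_positions(self, std_chrom, identity):
        ref_ids = [lu.id for lu in std_chrom.lus]
        n = len(ref_ids)
        for kind in ("deletion", "inversion", "duplication"):
            for i in range(n):
                for j in (i, min(i + 2, n - 1)):
                    ev = RecombinationEvent(kind, (i, j))
                    try:
                        arr = apply_event(identity, ev)
                    except Exception:
                        continue
                    comp = compare_arrangements(ref_ids, arr)
                    assert len(comp.events) == 1, (kind, i, j, comp.events)
                    assert comp.events[0]["kind"] == kind
                    assert set(comp.events[0]["lu_ids"]) == set(ref_ids[i: j + 1])


class TestSelection:
    ROWS = {
        "s1": [1, 1, 1, 0, 0, 0, 0, 0],
        "s2": [0, 1, 1, 1, 1, 1, 1, 1],
        "s3": [1, 1, 1, 1, 0, 1, 1, 0],
        "s4": [0, 1, 1, 0, 1, 1, 1, 0],
        "s5": [0, 1, 0, 1, 0, 0, 0, 0],
        "s6": [0, 0, 0, 0, 0, 1, 1, 1],
    }

    def _matrix(self, rows=None):
        df = pd.DataFrame.from_dict(rows or self.ROWS, orient="index", columns=JUNCTIONS_8)
        return GenotypeMatrix(df)

    def test_diversity_score_counts_zeros(self):
        assert diversity_score([1, 0, 0, 1, 0]) == 3

    def test_k1_picks_max_score(self):
        rows = {"a": [1] * 8, "b": _row({0, 1, 2}), "c": _row({4, 5, 6, 7, 3})}
        sel = select_candidates(self._matrix(rows), 1)
        assert list(sel["sample"]) == ["c"]

    def test_k3_matches_exhaustive_max_min_search(self):
        # oracle: brute force over all 3-subsets; frozen optimum = 4
        sel = select_candidates(self._matrix(), 3)
        arrs = {k: np.array(v) for k, v in self.ROWS.items()}

        def minpair(ss):
            return min((arrs[a] != arrs[b]).sum() for a, b in itertools.combinations(ss, 2))

        brute = max(minpair(s) for s in itertools.combinations(self.ROWS, 3))
        assert brute == 4
        assert minpair(tuple(sel["sample"])) == brute

    def test_identical_rows_flagged_redundant(self):
        rows = {"a": _row({0, 1}), "b": _row({0, 1})}
        sel = select_candidates(self._matrix(rows), 2)
        assert sel.iloc[1]["min_hamming_to_selected"] == 0
        assert bool(sel.iloc[1]["redundant"])

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            select_candidates(self._matrix(), 0)
        with pytest.raises(ValueError, match="exceeds"):
            select_candidates(self._matrix(), 7)

    def test_deterministic(self):
        a = select_candidates(self._matrix(), 4)
        b = select_candidates(self._matrix(), 4)
        assert a.equals(b)


def _end_to_end_reports(std_chrom, std_panel, events_per_sample):
    """Render single-event isolates, genotype, classify; return truth logs +
    reports in the crosscheck's expected shapes."""
    identity = LUArrangement.identity(std_chrom)
    logs, reports = [], []
    for name, ev in events_per_sample.items():
        arr = apply_event(identity, ev)
        seq = render(arr, std_chrom)
        m = genotype([(name, seq)], std_panel)
        reports.append(classify_pattern(m.row(name), std_panel.junction_ids(), sample=name))
        logs.append({"name": name, "events": [{
            "kind": ev.kind, "lu_span": list(ev.lu_span),
            "lu_ids": [f"LU{k}" for k in range(ev.lu_span[0], ev.lu_span[1] + 1)],
            "target_pos": ev.target_pos, "target_orientation": ev.target_orientation}]})
    return logs, reports


class TestCrosscheck:
    def test_single_lu_deletions_all_recovered(self, std_chrom, std_panel):
        events = {f"d{k}": RecombinationEvent("deletion", (k, k)) for k in range(1, 11)}
        logs, reports = _end_to_end_reports(std_chrom, std_panel, events)
        summary = insilico_crosscheck(logs, reports)
        assert (summary["true_positive"] == 1).all()
        assert (summary["false_positive"] == 0).all()
        assert (summary["false_negative"] == 0).all()

    def test_tandem_duplications_are_blind_spots(self, std_chrom, std_panel):
        events = {f"u{k}": RecombinationEvent("duplication", (k, k)) for k in range(1, 6)}
        logs, reports = _end_to_end_reports(std_chrom, std_panel, events)
        for rep in reports:  # all-present rows
            assert rep.n_missing == 0
        summary = insilico_crosscheck(logs, reports)
        assert (summary["blind_spot"] == 1).all()
        assert (summary[["true_positive", "false_negative", "false_positive"]] == 0).all().all()

    def test_multi_lu_inversions_recovered_as_ambiguous(self, std_chrom, std_panel):
        events = {f"i{k}": RecombinationEvent("inversion", (k, k + 2)) for k in range(1, 8)}
        logs, reports = _end_to_end_reports(std_chrom, std_panel, events)
        for rep in reports:
            assert [c["kind_hypothesis"] for c in rep.candidates] == ["inversion_or_translocation"]
        summary = insilico_crosscheck(logs, reports)
        assert (summary["ambiguous"] == 1).all()
        assert (summary["false_negative"] == 0).all()

    def test_single_lu_inversion_span_contains_true_lu(self, std_chrom, std_panel):
        # the two missing junctions are adjacent, so the hypothesis label is
        # "deletion"; the inferred span must still contain the inverted LU
        events = {"i5": RecombinationEvent("inversion", (5, 5))}
        logs, reports = _end_to_end_reports(std_chrom, std_panel, events)
        assert len(reports[0].candidates) == 1
        assert "LU5" in reports[0].candidates[0]["inferred_lu_span"]
        summary = insilico_crosscheck(logs, reports)
        assert int(summary.iloc[0]["ambiguous"]) == 1

    def test_circular_single_lu_deletions_end_to_end(self, circ_chrom, circ_panel):
        # every deletion, including ones flanking the origin, yields one
        # (possibly wrapped) run of 2 and the correct LU hypothesis
        identity = LUArrangement.identity(circ_chrom)
        ref_ids = [lu.id for lu in circ_chrom.lus]
        for k in range(len(circ_chrom.lus)):
            arr = apply_event(identity, RecombinationEvent("deletion", (k, k)))
            seq = render(arr, circ_chrom)
            row = genotype([("s", seq)], circ_panel, topology="circular").row("s")
            rep = classify_pattern(row, circ_panel.junction_ids(),
                                   topology="circular", sample="s")
            assert [c["kind_hypothesis"] for c in rep.candidates] == ["deletion"], (k, row)
            assert rep.candidates[0]["inferred_lu_span"] == [f"LU{k}"]
            comp = compare_arrangements(ref_ids, arr)
            assert comp.counts == {"deletions": 1, "inversions": 0, "complex": 0}

    def test_name_mismatch_rejected(self, std_chrom, std_panel):
        logs, reports = _end_to_end_reports(
            std_chrom, std_panel, {"x": RecombinationEvent("deletion", (2, 2))})
        logs[0]["name"] = "y"
        with pytest.raises(ValueError, match="namespace"):
            insilico_crosscheck(logs, reports)
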