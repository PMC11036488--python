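"""Interpretation of junction presence/absence patterns and of known signed
LU arrangements.

Two complementary views of a rearranged chromosome:

* :func:`classify_pattern` sees only the binary amplicon row and proposes
  candidate events. A run of >= 2 consecutive missing junctions suggests a
  deletion of the LUs between its flanking junctions; exactly two isolated
  missing junctions suggest an inverted or translocated block between them
  (the assay cannot separate the two); duplications are structurally
  invisible (both junction copies still amplify).

* :func:`compare_arrangements` sees the full signed LU order (e.g. from an
  assembly or a simulator truth log) and produces a parsimonious greedy
  annotation: deletions from the LU multiset difference, in-place reversed
  sign-flipped blocks as inversions, extra reference-consistent copies as
  duplications, and remaining out-of-place blocks as translocations
  (duplications + translocations are tallied as "complex").
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_model import LUArrangement

__all__ = [
    "EventCallReport",
    "ArrangementComparison",
    "classify_pattern",
    "compare_arrangements",
    "diversity_score",
    "select_candidates",
    "insilico_crosscheck",
]

DUPLICATION_CAVEAT = ("duplications are undetectable by junction presence/absence "
                      "(both junction copies still amplify)")


@dataclass
class EventCallReport:
    sample: str
    candidates: list[dict]
    n_missing: int
    diversity_score: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ArrangementComparison:
    sample: str
    counts: dict
    events: list[dict]
    breakpoints: int

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_junction(jid: str) -> tuple[int, int]:
    m = re.fullmatch(r"\[(\d+):(\d+)\]", jid)
    if not m:
        raise ValueError(f"junction id {jid!r} not of the form '[i:j]'")
    return int(m.group(1)), int(m.group(2))


def _zero_runs(row: list[int], circular: bool) -> list[list[int]]:
    """Maximal runs of 0s as lists of positions; for circular rows a run may
    wrap from the last junction to the first."""
    n = len(row)
    runs = []
    cur: list[int] = []
    for k in range(n):
        if row[k] == 0:
            cur.append(k)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    return runs


def classify_pattern(presence_row: list[int], junction_ids: list[str],
                     topology: str = "linear", sample: str = "") -> EventCallReport:
    """Turn one sample's presence row into candidate event calls.

    Rules, in order: (1) find maximal runs of consecutive missing junctions
    (wrapping for circular); (2) each run of length >= 2 -> one deletion
    candidate for the LUs between its flanking junctions; (3) exactly two
    singleton runs -> one explicitly ambiguous inversion_or_translocation
    candidate for the block between them; (4) any other singleton run ->
    indeterminate; (5) no missing junction -> "none" with the duplication
    blind-spot caveat. Candidates are ranked by run length, descending.
    """
    if len(presence_row) != len(junction_ids):
        raise ValueError(f"row length {len(presence_row)} != panel size {len(junction_ids)}")
    row = [int(v) for v in presence_row]
    if any(v not in (0, 1) for v in row):
        raise ValueError("presence row must be binary")
    circular = topology == "circular"
    bounds = [_parse_junction(j) for j in junction_ids]
    runs = _zero_runs(row, circular)
    n_missing = sum(1 for v in row if v == 0)

    candidates: list[dict] = []
    singles = [r for r in runs if len(r) == 1]
    for run in runs:
        if len(run) < 2:
            continue
        first_left = bounds[run[0]][0]
        j1 = bounds[run[0]][1]
        i2 = bounds[run[-1]][0]
        note = ("a run of exactly 2 missing junctions may also be a single-LU "
                "inversion or translocation" if len(run) == 2 else "")
        candidates.append({
            "kind_hypothesis": "deletion",
            "junction_run": [junction_ids[k] for k in run],
            "inferred_lu_span": _lu_range(j1, i2),
            "confidence_note": note,
        })
    if len(singles) == 2:
        (a_run, b_run) = singles
        a, b = a_run[0], b_run[0]
        j1 = bounds[a][1]
        i2 = bounds[b][0]
        note = "inversion and translocation are indistinguishable from this pattern"
        span = _lu_range(j1, i2)
        if circular:
            # two arcs are possible; hypothesize the shorter one
            inner = b - a - 1
            outer = len(row) - (b - a) - 1
            if outer < inner:
                span = _lu_range(bounds[b][1], bounds[a][0])
                note += "; shorter (wrapping) arc reported, complementary arc possible"
            else:
                note += f"; complementary arc LU{bounds[b][1]}..LU{bounds[a][0]} possible"
        candidates.append({
            "kind_hypothesis": "inversion_or_translocation",
            "junction_run": [junction_ids[a], junction_ids[b]],
            "inferred_lu_span": span,
            "confidence_note": note,
        })
    else:
        for run in singles:
            k = run[0]
            candidates.append({
                "kind_hypothesis": "indeterminate",
                "junction_run": [junction_ids[k]],
                "inferred_lu_span": _lu_range(bounds[k][0], bounds[k][1]),
                "confidence_note": "possible assay failure, small-LU event, or complex-event boundary",
            })
    if not runs:
        candidates.append({
            "kind_hypothesis": "none",
            "junction_run": [],
            "inferred_lu_span": [],
            "confidence_note": DUPLICATION_CAVEAT,
        })
    candidates.sort(key=lambda c: -len(c["junction_run"]))
    return EventCallReport(sample=sample, candidates=candidates,
                           n_missing=n_missing, diversity_score=n_missing)


def _lu_range(lo: int, hi: int) -> list[str]:
    if hi < lo:
        return [f"LU{lo}", f"LU{hi}"]  # wrapping span endpoints (circular)
    return [f"LU{k}" for k in range(lo, hi + 1)]


# ---------------------------------------------------------------------------
# signed-arrangement comparison


def _adjacent_ok(a: tuple[str, str], b: tuple[str, str], pos: dict[str, int]) -> bool:
    if a[1] == "+" and b[1] == "+":
        return pos[b[0]] == pos[a[0]] + 1
    if a[1] == "-" and b[1] == "-":
        return pos[b[0]] == pos[a[0]] - 1
    return False


def _blocks(units: list[tuple[str, str]], pos: dict[str, int]):
    """Maximal reference-consistent oriented runs: (start_index, units)."""
    out = []
    i = 0
    while i < len(units):
        j = i
        while j + 1 < len(units) and _adjacent_ok(units[j], units[j + 1], pos):
            j += 1
        out.append((i, units[i: j + 1]))
        i = j + 1
    return out


def _max_weight_increasing(keys: list[int], weights: list[int]) -> set[int]:
    """Indices of the max-weight strictly-increasing subsequence; among ties
    the lexicographically smallest index set (deterministic anchor choice)."""
    n = len(keys)
    best: list[tuple[int, tuple[int, ...]]] = [(0, ())] * n
    for i in range(n):
        w, chain = weights[i], (i,)
        cand = (weights[i], (i,))
        for p in range(i):
            if keys[p] < keys[i]:
                pw, pc = best[p]
                c = (pw + weights[i], pc + (i,))
                if c[0] > cand[0] or (c[0] == cand[0] and c[1] < cand[1]):
                    cand = c
        best[i] = cand
    if not n:
        return set()
    top = max(b[0] for b in best)
    chains = sorted(c for w, c in best if w == top)
    return set(chains[0])


def compare_arrangements(reference_lu_order: list[str], observed: LUArrangement,
                         sample: str = "") -> ArrangementComparison:
    """Greedy event annotation of an observed signed arrangement against the
    reference LU order. Not a minimal rearrangement-distance solver: for
    multi-event histories the annotation is parsimonious, not provably
    minimal.
    """
    pos = {lu: k for k, lu in enumerate(reference_lu_order)}
    if len(pos) != len(reference_lu_order):
        raise ValueError("reference LU order contains duplicates")
    for lu, _ in observed.units:
        if lu not in pos:
            raise ValueError(f"unknown LU id {lu!r} in observed arrangement")

    events: list[dict] = []
    obs = list(observed.units)

    # (c) deletions: reference-consecutive groups of LUs absent from the multiset
    counts = Counter(lu for lu, _ in obs)
    missing = sorted(pos[lu] for lu in reference_lu_order if counts.get(lu, 0) == 0)
    deleted_set = {reference_lu_order[k] for k in missing}
    for grp in _group_consecutive(missing):
        events.append({"kind": "deletion",
                       "lu_ids": [reference_lu_order[k] for k in grp]})

    # (e) duplications: greedily remove maximal reference-consistent blocks of
    # surplus copies, preferring the copy whose removal heals the flanking
    # adjacency (so the kept copy is the best-embedded one)
    extra_idx: set[int] = set()
    surplus = {lu: c - 1 for lu, c in counts.items() if c > 1}
    while sum(surplus.values()) > 0:
        candidates = []
        t = 0
        while t < len(obs):
            if t in extra_idx or surplus.get(obs[t][0], 0) <= 0:
                t += 1
                continue
            u = t
            while (u + 1 < len(obs) and u + 1 not in extra_idx
                   and surplus.get(obs[u + 1][0], 0) > 0
                   and _adjacent_ok(obs[u], obs[u + 1], pos)):
                u += 1
            candidates.append((t, u))
            t = u + 1
        if not candidates:
            break

        def residual_breakpoints(tu):
            t, u = tu
            keep = [obs[x] for x in range(len(obs))
                    if x not in extra_idx and not t <= x <= u]
            return sum(1 for a, b in zip(keep, keep[1:]) if not _adjacent_ok(a, b, pos))

        # the copy to remove: fewest leftover breakpoints, then longest block
        # (parsimony), then latest copy
        t, u = sorted(candidates,
                      key=lambda tu: (residual_breakpoints(tu), -(tu[1] - tu[0]), -tu[0]))[0]
        block = obs[t: u + 1]
        for lu, _ in block:
            surplus[lu] -= 1
        extra_idx.update(range(t, u + 1))
        events.append({"kind": "duplication",
                       "lu_ids": [lu for lu, _ in block],
                       "orientation": block[0][1]})

    reduced = [u for t, u in enumerate(obs) if t not in extra_idx]

    # (b, d, f) block decomposition, in-place inversions, translocations
    blocks = _blocks(reduced, pos)
    fwd_blocks = []
    for bi, (start, block) in enumerate(blocks):
        inverted = block[0][1] == "-"
        if not inverted:
            fwd_blocks.append((bi, start, block))
            continue
        lo = pos[block[-1][0]]
        hi = pos[block[0][0]]
        left_nb = reduced[start - 1][0] if start > 0 else None
        right_nb = reduced[start + len(block)][0] if start + len(block) < len(reduced) else None
        exp_left = _nearest_surviving(reference_lu_order, lo - 1, -1, deleted_set)
        exp_right = _nearest_surviving(reference_lu_order, hi + 1, +1, deleted_set)
        if left_nb == exp_left and right_nb == exp_right:
            events.append({"kind": "inversion", "lu_ids": [reference_lu_order[k] for k in range(lo, hi + 1)]})
        else:
            events.append({"kind": "translocation",
                           "lu_ids": [lu for lu, _ in block], "orientation": "-"})
    anchors = _max_weight_increasing(
        [pos[b[2][0][0]] for b in fwd_blocks],
        [len(b[2]) for b in fwd_blocks])
    for rank, (bi, start, block) in enumerate(fwd_blocks):
        if rank not in anchors:
            events.append({"kind": "translocation",
                           "lu_ids": [lu for lu, _ in block], "orientation": "+"})

    # breakpoints: observed adjacencies absent from the signed reference set
    breakpoints = 0
    pairs = list(zip(obs, obs[1:]))
    if observed.topology == "circular" and len(obs) > 1:
        pairs.append((obs[-1], obs[0]))
    wrap_ok = observed.topology == "circular"
    nref = len(reference_lu_order)
    for a, b in pairs:
        ok = _adjacent_ok(a, b, pos)
        if not ok and wrap_ok:  # reference wrap adjacency (last -> first)
            if a[1] == "+" and b[1] == "+" and pos[a[0]] == nref - 1 and pos[b[0]] == 0:
                ok = True
            if a[1] == "-" and b[1] == "-" and pos[a[0]] == 0 and pos[b[0]] == nref - 1:
                ok = True
        if not ok:
            breakpoints += 1

    tallies = Counter(e["kind"] for e in events)
    counts_out = {"deletions": tallies["deletion"], "inversions": tallies["inversion"],
                  "complex": tallies["duplication"] + tallies["translocation"]}
    return ArrangementComparison(sample=sample, counts=counts_out,
                                 events=events, breakpoints=breakpoints)


def _group_consecutive(sorted_positions: list[int]) -> list[list[int]]:
    groups: list[list[int]] = []
    for p in sorted_positions:
        if groups and p == groups[-1][-1] + 1:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def _nearest_surviving(ref_order: list[str], start: int, step: int, deleted: set) -> str | None:
    k = start
    while 0 <= k < len(ref_order):
        if ref_order[k] not in deleted:
            return ref_order[k]
        k += step
    return None


# ---------------------------------------------------------------------------
# diversity scoring and candidate selection


def diversity_score(presence_row: list[int]) -> int:
    """Number of missing junctions — a cheap proxy for how rearranged a
    sample is."""
    return sum(1 for v in presence_row if int(v) == 0)


def select_candidates(matrix, k: int) -> pd.DataFrame:
    """Greedy max-min-Hamming selection of ``k`` diverse samples.

    Seed with the highest-scoring sample (ties: lexicographic name), then
    repeatedly add the sample maximizing the minimum Hamming distance to the
    chosen set (ties: higher score, then name). A pick at distance 0 from
    the chosen set is flagged redundant.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    n = len(df)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rows = {name: np.asarray(df.loc[name], dtype=int) for name in df.index}
    scores = {name: int((v == 0).sum()) for name, v in rows.items()}

    first = sorted(df.index, key=lambda s: (-scores[s], s))[0]
    chosen = [first]
    records = [{"sample": first, "diversity_score": scores[first],
                "min_hamming_to_selected": None, "redundant": False}]
    while len(chosen) < k:
        best_name, best_key, best_d = None, None, None
        for name in df.index:
            if name in chosen:
                continue
            d = min(int((rows[name] != rows[c]).sum()) for c in chosen)
            key = (-d, -scores[name], name)
            if best_key is None or key < best_key:
                best_name, best_key, best_d = name, key, d
        chosen.append(best_name)
        records.append({"sample": best_name, "diversity_score": scores[best_name],
                        "min_hamming_to_selected": best_d, "redundant": best_d == 0})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# truth-vs-call crosscheck


def insilico_crosscheck(truth_logs: list[dict], reports: list[EventCallReport],
                        tagged_junctions: list[str] | None = None) -> pd.DataFrame:
    """Tally candidate calls against simulator truth, per sample.

    Blind spots — duplications, and events whose junctions carry no tag —
    are excluded from the denominator and counted separately. A truth
    deletion matched by a deletion candidate overlapping its LUs is a true
    positive; an inversion or translocation matched by any overlapping
    candidate counts as recovered-with-ambiguity; unmatched truth events are
    false negatives; candidates matching no truth event are false positives.
    """
    by_name = {rec["name"]: rec for rec in truth_logs}
    report_names = {r.sample for r in reports}
    missing = report_names.symmetric_difference(by_name)
    if missing:
        raise ValueError(f"sample namespace mismatch between truth and reports: {sorted(missing)}")
    tagged_lus: set[str] | None = None
    if tagged_junctions is not None:
        tagged_lus = set()
        for jid in tagged_junctions:
            i, j = _parse_junction(jid)
            tagged_lus.add(f"LU{i}")
            tagged_lus.add(f"LU{j}")

    rows = []
    for rep in sorted(reports, key=lambda r: r.sample):
        truth = by_name[rep.sample]["events"]
        tp = fn = ambiguous = blind = fp = 0
        real_candidates = [c for c in rep.candidates
                           if c["kind_hypothesis"] in ("deletion", "inversion_or_translocation")]
        matched_candidates: set[int] = set()
        for ev in truth:
            if ev["kind"] == "duplication":
                blind += 1
                continue
            ev_lus = set(ev["lu_ids"])
            if tagged_lus is not None and not (ev_lus & tagged_lus):
                blind += 1
                continue
            hit = None
            for ci, cand in enumerate(real_candidates):
                if ev_lus & set(cand["inferred_lu_span"]):
                    hit = (ci, cand)
                    break
            if hit is None:
                fn += 1
                continue
            matched_candidates.add(hit[0])
            if ev["kind"] == "deletion" and hit[1]["kind_hypothesis"] == "deletion":
                tp += 1
            else:
                ambiguous += 1
        fp = len(real_candidates) - len(matched_candidates)
        rows.append({"sample": rep.sample, "true_positive": tp, "ambiguous": ambiguous,
                     "false_negative": fn, "false_positive": fp, "blind_spot": blind})
    return pd.DataFrame.from_records(rows)
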