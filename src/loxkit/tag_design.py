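"""Junction-spanning diagnostic primer design.

For every motif junction of an annotated chromosome, design one qPCR primer
pair whose amplicon spans the motif copy (``span_motif`` mode), falling back
to a wider multi-motif amplicon when the flanking LU is too short to host a
primer. ``within_unit`` mode instead places both primers inside a single LU
(the classic within-segment assay, which can only report deletions).

Selection is exhaustive and deterministic: every primer placement satisfying
the hard constraints (length, Tm, GC, mask, amplicon size) is enumerated and
the pair minimizing

    w_len*(|len_f - opt| + |len_r - opt|)
  + w_tm *(|Tm_f - opt| + |Tm_r - opt|)
  + w_gc *(gc dist-to-range, both primers)
  + w_pair*|Tm_f - Tm_r|

is returned, with ties broken by smaller forward start, then shorter
amplicon, then lexicographic primer sequence.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .genome_model import AnnotatedChromosome, revcomp

__all__ = [
    "DesignParams",
    "PrimerPair",
    "FailedJunction",
    "TagPanel",
    "melting_temp",
    "mask",
    "design_tags",
    "offtarget_scan",
    "write_panel_csv",
    "read_panel_csv",
]

PANEL_COLUMNS = [
    "junction_id", "fwd_seq", "rev_seq", "fwd_start", "fwd_end",
    "rev_start", "rev_end", "amplicon_len", "tm_fwd", "tm_rev",
    "gc_fwd", "gc_rev", "spans_motifs", "penalty",
    "offtarget_fwd_hits", "offtarget_rev_hits", "spurious_amplicon", "status",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class DesignParams:
    """Design constraints and penalty weights. All values overridable from a
    YAML config (see :meth:`from_yaml`)."""

    primer_len: tuple[int, int, int] = (18, 20, 25)       # min, opt, max
    tm: tuple[float, float, float] = (57.0, 60.0, 63.0)   # min, opt, max  (deg C)
    gc: tuple[float, float] = (0.30, 0.70)                # min, max fraction
    amplicon_len: tuple[int, int] = (100, 500)            # min, max bp
    max_offtarget_mismatch: int = 4
    max_span_motifs: int = 2
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 1.0
    w_pair: float = 1.0
    salt_mM: float = 50.0
    primer_conc_nM: float = 250.0

    def __post_init__(self):
        self.primer_len = tuple(self.primer_len)
        self.tm = tuple(self.tm)
        self.gc = tuple(self.gc)
        self.amplicon_len = tuple(self.amplicon_len)
        for trip, label in ((self.primer_len, "primer_len"), (self.tm, "tm")):
            if not trip[0] <= trip[1] <= trip[2]:
                raise ValueError(f"{label}: need min <= opt <= max, got {trip}")
        if not self.gc[0] <= self.gc[1]:
            raise ValueError(f"gc: need min <= max, got {self.gc}")
        if not self.amplicon_len[0] <= self.amplicon_len[1]:
            raise ValueError(f"amplicon_len: need min <= max, got {self.amplicon_len}")

    @classmethod
    def from_yaml(cls, path) -> "DesignParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "primer_len": list(self.primer_len), "tm": list(self.tm),
            "gc": list(self.gc), "amplicon_len": list(self.amplicon_len),
            "max_offtarget_mismatch": self.max_offtarget_mismatch,
            "max_span_motifs": self.max_span_motifs,
            "w_len": self.w_len, "w_tm": self.w_tm, "w_gc": self.w_gc,
            "w_pair": self.w_pair, "salt_mM": self.salt_mM,
            "primer_conc_nM": self.primer_conc_nM,
        }


@dataclass
class PrimerPair:
    junction_id: str
    fwd_seq: str
    rev_seq: str
    fwd_interval: tuple[int, int]
    rev_interval: tuple[int, int]
    amplicon_len: int
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    spans_motifs: int
    penalty: float
    offtarget_fwd_hits: int | None = None
    offtarget_rev_hits: int | None = None
    spurious_amplicon: bool | None = None

    @property
    def multi_match(self) -> bool:
        """True once off-target screened and either primer has >1 genomic match."""
        return bool((self.offtarget_fwd_hits or 0) > 1 or (self.offtarget_rev_hits or 0) > 1)


@dataclass
class FailedJunction:
    junction_id: str
    reason: str  # no_fwd_window | no_rev_window | no_pair_in_amplicon_range | masked_out


@dataclass
class TagPanel:
    reference: str
    motif: str
    pairs: list[PrimerPair]
    failed: list[FailedJunction] = field(default_factory=list)
    mode: str = "span_motif"

    def __post_init__(self):
        ids = [p.junction_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate junction ids in panel")

    def junction_ids(self) -> list[str]:
        return [p.junction_id for p in self.pairs]


# ---------------------------------------------------------------------------
# melting temperature — unified nearest-neighbor parameters with
# monovalent-salt entropy correction

# kcal/mol, cal/(mol*K); unified duplex parameters (SantaLucia 1998)
_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT_GC = (0.1, -2.8)   # per G/C terminus
_INIT_AT = (2.3, 4.1)    # per A/T terminus
_R_GAS = 1.98722         # cal/(mol*K)


def melting_temp(primer: str, salt_mM: float = 50.0, primer_conc_nM: float = 250.0) -> float:
    """Nearest-neighbor melting temperature in deg C.

    Enthalpy/entropy sums over dinucleotide stacks with terminal initiation
    terms, entropy-based monovalent-salt correction
    (``0.368 * (N-1) * ln[Na+]``) and total-strand concentration term
    ``R * ln(CT/4)`` (``CT`` for a self-complementary primer).
    """
    seq = primer.upper()
    if len(seq) < 8:
        raise ValueError(f"primer too short for a Tm estimate: {len(seq)} < 8 nt")
    if re.search("[^ACGT]", seq):
        raise ValueError("primer must contain only ACGT")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        stack = seq[i:i + 2]
        dh += _NN_DH[stack]
        ds += _NN_DS[stack]
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    self_comp = seq == revcomp(seq)
    if self_comp:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    ct = primer_conc_nM * 1e-9
    denom = ds + _R_GAS * math.log(ct if self_comp else ct / 4.0)
    return dh * 1000.0 / denom - 273.15


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# masking


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _dust_intervals(seq: str, threshold: float, window: int = 64, step: int = 32) -> list[tuple[int, int]]:
    # trinucleotide-repetitiveness score per window: sum c*(c-1)/2 over
    # triplet counts, normalized by (#triplets - 1)
    hits = []
    n = len(seq)
    for lo in range(0, max(1, n - 2), step):
        win = seq[lo: lo + window]
        k = len(win) - 2
        if k < 2:
            break
        counts: dict[str, int] = {}
        for i in range(k):
            t = win[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) for c in counts.values()) / 2.0 / (k - 1)
        if score > threshold:
            hits.append((lo, lo + len(win)))
    return hits


def mask(sequence: str, homopolymer_min_run: int = 6, dust_threshold: float = 2.0,
         user_bed: list[tuple[int, int]] | None = None) -> list[tuple[int, int]]:
    """Intervals excluded from primer placement.

    Union of homopolymer runs of length >= ``homopolymer_min_run``,
    low-complexity windows whose trinucleotide-repetitiveness score exceeds
    ``dust_threshold``, runs of N, and any user-supplied intervals.
    """
    seq = sequence.upper()
    intervals: list[tuple[int, int]] = []
    if homopolymer_min_run >= 2:
        pat = re.compile(r"([ACGT])\1{%d,}" % (homopolymer_min_run - 1))
        intervals.extend(m.span() for m in pat.finditer(seq))
    intervals.extend(m.span() for m in re.finditer("N+", seq))
    if dust_threshold is not None:
        intervals.extend(_dust_intervals(seq, dust_threshold))
    if user_bed:
        for s, e in user_bed:
            if s < 0 or e > len(seq) or s >= e:
                raise ValueError(f"user mask interval ({s}, {e}) outside sequence of length {len(seq)}")
            intervals.append((int(s), int(e)))
    return _merge_intervals(intervals)


# ---------------------------------------------------------------------------
# design


def _mask_bool(length: int, masked: list[tuple[int, int]] | None) -> np.ndarray:
    arr = np.zeros(length, dtype=bool)
    for s, e in masked or []:
        arr[max(0, s): min(length, e)] = True
    return arr


class _Region:
    """Unrolled coordinate access into a (possibly circular) chromosome."""

    def __init__(self, chrom: AnnotatedChromosome, maskarr: np.ndarray):
        self.seq = chrom.sequence
        self.L = len(chrom.sequence)
        self.circular = chrom.topology == "circular"
        self.maskarr = maskarr

    def extract(self, start: int, end: int) -> str:
        if not self.circular:
            return self.seq[start:end]
        idx = np.arange(start, end) % self.L
        return "".join(self.seq[i] for i in idx)

    def is_masked(self, start: int, end: int) -> bool:
        if not self.circular:
            return bool(self.maskarr[start:end].any())
        return bool(self.maskarr[np.arange(start, end) % self.L].any())


def _primer_candidates(region: _Region, lo: int, hi: int, params: DesignParams,
                       reverse: bool):
    """All primers within unrolled region [lo, hi) passing per-primer hard
    constraints. Returns parallel lists (start, end, seq, tm, gc, penalty)."""
    lmin, lopt, lmax = params.primer_len
    tmin, topt, tmax = params.tm
    gmin, gmax = params.gc
    out = []
    if hi - lo < lmin:
        return out
    window = region.extract(lo, hi)
    for length in range(lmin, min(lmax, hi - lo) + 1):
        for off in range(0, hi - lo - length + 1):
            s, e = lo + off, lo + off + length
            sub = window[off: off + length]
            if "N" in sub:
                continue
            gc = _gc_fraction(sub)
            if not gmin <= gc <= gmax:
                continue
            tm = melting_temp(sub, params.salt_mM, params.primer_conc_nM)
            if not tmin <= tm <= tmax:
                continue
            if region.is_masked(s, e):
                continue
            seq = revcomp(sub) if reverse else sub
            pen = (params.w_len * abs(length - lopt)
                   + params.w_tm * abs(tm - topt)
                   + params.w_gc * max(0.0, gmin - gc, gc - gmax))
            out.append((s, e, seq, tm, gc, pen))
    return out


def _best_pair(fwds, revs, params: DesignParams):
    """Penalty-minimal (fwd, rev) pair with amplicon length within bounds.

    Ties: smaller fwd start, then shorter amplicon, then lexicographic
    fwd_seq, then rev_seq. Returns (fwd, rev, penalty) or None.
    """
    if not fwds or not revs:
        return None
    amin, amax = params.amplicon_len
    rev_ends = np.array([r[1] for r in revs])
    order = np.argsort(rev_ends, kind="stable")
    rev_ends = rev_ends[order]
    revs_sorted = [revs[i] for i in order]
    rev_pen = np.array([r[5] for r in revs_sorted])
    rev_tm = np.array([r[3] for r in revs_sorted])

    best = None
    best_key = None
    for f in fwds:
        fs, fe, fseq, ftm, fgc, fpen = f
        j0 = np.searchsorted(rev_ends, fs + amin, side="left")
        j1 = np.searchsorted(rev_ends, fs + amax, side="right")
        if j0 >= j1:
            continue
        tot = fpen + rev_pen[j0:j1] + params.w_pair * np.abs(ftm - rev_tm[j0:j1])
        jrel = int(np.argmin(tot))
        cand_idx = np.flatnonzero(tot <= tot[jrel] + 1e-12) + j0
        for j in cand_idx:
            r = revs_sorted[j]
            pen = fpen + r[5] + params.w_pair * abs(ftm - r[3])
            key = (round(pen, 9), fs, r[1] - fs, fseq, r[2])
            if best_key is None or key < best_key:
                best_key = key
                best = (f, r, pen)
    return best


def design_tags(chromosome: AnnotatedChromosome, params: DesignParams | None = None,
                masked: list[tuple[int, int]] | None = None,
                mode: str = "span_motif") -> TagPanel:
    """Design one diagnostic primer pair per junction (or per LU in
    ``within_unit`` mode). See module docstring for the objective.

    In ``span_motif`` mode, when no pair fits around a single motif (flanking
    LU too short), the search widens to amplicons spanning up to
    ``params.max_span_motifs`` consecutive motifs; junctions that still fail
    are recorded with a machine-readable reason.
    """
    params = params or DesignParams()
    if mode not in ("span_motif", "within_unit"):
        raise ValueError(f"unknown design mode {mode!r}")
    L = len(chromosome.sequence)
    if L < params.amplicon_len[0]:
        raise ValueError(f"chromosome {chromosome.name} shorter than the minimum amplicon")
    region = _Region(chromosome, _mask_bool(L, masked))

    if mode == "within_unit":
        return _design_within_unit(chromosome, params, region)

    sites = chromosome.motif_sites
    n = len(sites)
    if n == 0:
        raise ValueError(f"{chromosome.name} has no motif junction to span")
    circular = chromosome.topology == "circular"
    mlen = len(chromosome.motif)
    amax = params.amplicon_len[1]

    def site_start(i):
        return sites[i % n][0] + (L if circular and i >= n else (-L if circular and i < 0 else 0))

    pairs: list[PrimerPair] = []
    failed: list[FailedJunction] = []
    for k in range(n):
        if circular:
            jid = f"[{(k - 1) % n}:{k}]"
        else:
            jid = f"[{k}:{k + 1}]"
        found = None
        saw_fwd = saw_rev = False
        any_window = False
        max_span = min(params.max_span_motifs, n - 1 if circular else n)
        for s in range(1, max_span + 1):
            window_pairs = []
            for t in range(s):
                w0, w1 = k - (s - 1) + t, k + t
                if not circular and (w0 < 0 or w1 > n - 1):
                    continue
                # unrolled coordinates of the motif window
                fs = sites[w0 % n][0]
                span = (sites[w1 % n][1] - fs) % L if circular else sites[w1][1] - fs
                le = fs + span
                # flanking-LU boundaries
                if circular:
                    up = fs - ((fs - sites[(w0 - 1) % n][1]) % L)
                    down = le + ((sites[(w1 + 1) % n][0] - (le % L)) % L)
                else:
                    up = sites[w0 - 1][1] if w0 > 0 else 0
                    down = sites[w1 + 1][0] if w1 < n - 1 else L
                any_window = True
                fwds = _primer_candidates(region, max(up, fs - amax), fs, params, reverse=False)
                revs = _primer_candidates(region, le, min(down, le + amax), params, reverse=True)
                saw_fwd = saw_fwd or bool(fwds)
                saw_rev = saw_rev or bool(revs)
                hit = _best_pair(fwds, revs, params)
                if hit:
                    window_pairs.append(hit)
            if window_pairs:
                window_pairs.sort(key=lambda h: (round(h[2], 9), h[0][0], h[1][1] - h[0][0], h[0][2], h[1][2]))
                f, r, pen = window_pairs[0]
                found = PrimerPair(
                    junction_id=jid, fwd_seq=f[2], rev_seq=r[2],
                    fwd_interval=(f[0] % L, f[0] % L + (f[1] - f[0])),
                    rev_interval=(r[0] % L, r[0] % L + (r[1] - r[0])),
                    amplicon_len=r[1] - f[0], tm_fwd=round(f[3], 3), tm_rev=round(r[3], 3),
                    gc_fwd=round(f[4], 4), gc_rev=round(r[4], 4),
                    spans_motifs=s, penalty=round(pen, 4))
                break
        if found:
            pairs.append(found)
        else:
            if not any_window:
                reason = "no_pair_in_amplicon_range"
            elif not saw_fwd:
                reason = "masked_out" if region.maskarr.any() else "no_fwd_window"
            elif not saw_rev:
                reason = "masked_out" if region.maskarr.any() else "no_rev_window"
            else:
                reason = "no_pair_in_amplicon_range"
            failed.append(FailedJunction(jid, reason))
    return TagPanel(chromosome.name, chromosome.motif.name, pairs, failed, mode="span_motif")


def _design_within_unit(chromosome: AnnotatedChromosome, params: DesignParams,
                        region: _Region) -> TagPanel:
    pairs = []
    failed = []
    L = len(chromosome.sequence)
    for lu_id, lo, hi in chromosome.lu_intervals():
        if hi - lo < params.amplicon_len[0]:
            failed.append(FailedJunction(lu_id, "no_pair_in_amplicon_range"))
            continue
        fwds = _primer_candidates(region, lo, hi, params, reverse=False)
        revs = _primer_candidates(region, lo, hi, params, reverse=True)
        # forward primer must sit upstream of (not overlap) the reverse primer
        hit = None
        if fwds and revs:
            hit = _best_pair(fwds, [r for r in revs], params)
            if hit and hit[1][0] < hit[0][1]:  # overlapping primers: re-search strictly
                best = None
                for f in fwds:
                    cands = [r for r in revs if r[0] >= f[1]
                             and params.amplicon_len[0] <= r[1] - f[0] <= params.amplicon_len[1]]
                    h = _best_pair([f], cands, params)
                    if h and (best is None or (round(h[2], 9), h[0][0], h[1][1] - h[0][0], h[0][2], h[1][2])
                              < (round(best[2], 9), best[0][0], best[1][1] - best[0][0], best[0][2], best[1][2])):
                        best = h
                hit = best
        if hit:
            f, r, pen = hit
            pairs.append(PrimerPair(
                junction_id=lu_id, fwd_seq=f[2], rev_seq=r[2],
                fwd_interval=(f[0] % L, f[0] % L + (f[1] - f[0])),
                rev_interval=(r[0] % L, r[0] % L + (r[1] - r[0])),
                amplicon_len=r[1] - f[0], tm_fwd=round(f[3], 3), tm_rev=round(r[3], 3),
                gc_fwd=round(f[4], 4), gc_rev=round(r[4], 4),
                spans_motifs=0, penalty=round(pen, 4)))
        else:
            reason = "no_fwd_window" if not fwds else ("no_rev_window" if not revs else "no_pair_in_amplicon_range")
            if region.maskarr[lo % L: hi % L].any() and (not fwds or not revs):
                reason = "masked_out"
            failed.append(FailedJunction(lu_id, reason))
    return TagPanel(chromosome.name, chromosome.motif.name, pairs, failed, mode="within_unit")


# ---------------------------------------------------------------------------
# off-target screening (exact brute force)

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _hamming_hits(ref: np.ndarray, primer: str, max_mismatch: int):
    """(positions, mismatches) of all windows of |primer| within ref at
    Hamming distance <= max_mismatch."""
    p = _encode(primer)
    k = len(p)
    if len(ref) < k:
        return np.array([], dtype=int), np.array([], dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(ref, k)
    mm = (windows != p).sum(axis=1)
    pos = np.flatnonzero(mm <= max_mismatch)
    return pos, mm[pos]


def offtarget_scan(panel: TagPanel, references: dict[str, str], max_mismatch: int = 4,
                   max_product: int = 1000, require_3prime_match: bool = True) -> TagPanel:
    """Exhaustive both-strand Hamming scan of every panel primer against every
    reference sequence.

    A primer matching more than once (<= ``max_mismatch`` mismatches) is
    flagged via its hit count; any unintended fwd/rev hit pair in amplifiable
    orientation within ``max_product`` flags the pair as a spurious amplicon.
    With ``require_3prime_match`` (default) an off-target site only counts
    toward spurious amplicons if the primer's 3'-terminal base matches
    exactly.
    """
    if not references:
        raise ValueError("off-target scan requires at least one reference sequence")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    encoded = {name: _encode(seq) for name, seq in references.items()}

    out_pairs = []
    for pair in panel.pairs:
        hits = {"fwd": [], "rev": []}  # (refname, pos, strand, three_prime_ok)
        for role, primer in (("fwd", pair.fwd_seq), ("rev", pair.rev_seq)):
            rc = revcomp(primer)
            for name, ref in encoded.items():
                pos, _mm = _hamming_hits(ref, primer, max_mismatch)
                for p in pos:
                    ok3 = ref[p + len(primer) - 1] == ord(primer[-1])
                    hits[role].append((name, int(p), "+", bool(ok3)))
                pos, _mm = _hamming_hits(ref, rc, max_mismatch)
                for p in pos:
                    ok3 = ref[p] == ord(rc[0])  # primer 3' end maps to window start
                    hits[role].append((name, int(p), "-", bool(ok3)))
        fwd_n, rev_n = len(hits["fwd"]), len(hits["rev"])

        intended_fwd = (panel.reference, pair.fwd_interval[0], "+")
        intended_rev = (panel.reference, pair.rev_interval[0], "-")
        spurious = False
        for (na, pa, sa, oka) in hits["fwd"]:
            if spurious:
                break
            for (nb, pb, sb, okb) in hits["rev"]:
                if na != nb or sa == sb:
                    continue
                if require_3prime_match and not (oka and okb):
                    continue
                if sa == "+":
                    start, end = pa, pb + len(pair.rev_seq)
                else:
                    start, end = pb, pa + len(pair.fwd_seq)
                if not 0 < end - start <= max_product:
                    continue
                if (na, pa, sa) == intended_fwd and (nb, pb, sb) == intended_rev:
                    continue
                spurious = True
                break
        out_pairs.append(replace(pair, offtarget_fwd_hits=fwd_n, offtarget_rev_hits=rev_n,
                                 spurious_amplicon=spurious))
    return TagPanel(panel.reference, panel.motif, out_pairs, list(panel.failed), mode=panel.mode)


# ---------------------------------------------------------------------------
# CSV round trip


def write_panel_csv(panel: TagPanel, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PANEL_COLUMNS)
        for p in panel.pairs:
            w.writerow([
                p.junction_id, p.fwd_seq, p.rev_seq,
                p.fwd_interval[0], p.fwd_interval[1], p.rev_interval[0], p.rev_interval[1],
                p.amplicon_len, p.tm_fwd, p.tm_rev, p.gc_fwd, p.gc_rev,
                p.spans_motifs, p.penalty,
                "" if p.offtarget_fwd_hits is None else p.offtarget_fwd_hits,
                "" if p.offtarget_rev_hits is None else p.offtarget_rev_hits,
                "" if p.spurious_amplicon is None else int(p.spurious_amplicon),
                "ok",
            ])
        for f in panel.failed:
            w.writerow([f.junction_id] + [""] * 16 + [f"failed:{f.reason}"])


def read_panel_csv(path, reference: str = "", motif: str = "") -> TagPanel:
    pairs = []
    failed = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        for row in reader:
            status = row["status"]
            if status.startswith("failed:"):
                failed.append(FailedJunction(row["junction_id"], status.split(":", 1)[1]))
                continue
            pairs.append(PrimerPair(
                junction_id=row["junction_id"], fwd_seq=row["fwd_seq"], rev_seq=row["rev_seq"],
                fwd_interval=(int(row["fwd_start"]), int(row["fwd_end"])),
                rev_interval=(int(row["rev_start"]), int(row["rev_end"])),
                amplicon_len=int(row["amplicon_len"]),
                tm_fwd=float(row["tm_fwd"]), tm_rev=float(row["tm_rev"]),
                gc_fwd=float(row["gc_fwd"]), gc_rev=float(row["gc_rev"]),
                spans_motifs=int(row["spans_motifs"]), penalty=float(row["penalty"]),
                offtarget_fwd_hits=int(row["offtarget_fwd_hits"]) if row["offtarget_fwd_hits"] else None,
                offtarget_rev_hits=int(row["offtarget_rev_hits"]) if row["offtarget_rev_hits"] else None,
                spurious_amplicon=bool(int(row["spurious_amplicon"])) if row["spurious_amplicon"] else None,
            ))
    return TagPanel(reference, motif, pairs, failed)
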