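"""Core data model: recombination motifs, annotated chromosomes, loxP-unit
segmentation, signed LU arrangements, sequence rendering, and synthetic
fixture generation.

Coordinate convention
---------------------
All intervals are 0-based, half-open ``[start, end)`` — internally, in BED
output, and in every table this package emits.

A *loxP unit* (LU) is the chromosome segment between two consecutive motif
copies. A linear chromosome with ``n`` motif sites has ``n + 1`` LUs; a
circular one has ``n`` (LU_0 begins immediately after motif site 0 and the
last LU wraps back to it).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOXPSYM",
    "Motif",
    "LoxUnit",
    "AnnotatedChromosome",
    "LUArrangement",
    "revcomp",
    "scan_motifs",
    "segment",
    "render",
    "generate_fixture",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_TOPOLOGIES = ("linear", "circular")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_topology(topology: str) -> None:
    if topology not in _VALID_TOPOLOGIES:
        raise ValueError(f"topology must be one of {_VALID_TOPOLOGIES}, got {topology!r}")


@dataclass(frozen=True)
class Motif:
    """A recombination recognition motif.

    Parameters
    ----------
    name : str
        Label, e.g. ``"loxPsym"``.
    sequence : str
        Motif sequence; ACGT only, length >= 8. Uppercased on construction.
    """

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 8:
            raise ValueError(f"motif {self.name!r}: length must be >= 8, got {len(self.sequence)}")
        if re.search("[^ACGT]", self.sequence):
            raise ValueError(f"motif {self.name!r}: sequence must contain only ACGT")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_palindromic(self) -> bool:
        """True iff the motif equals its own reverse complement."""
        return self.sequence == revcomp(self.sequence)


#: The default 34 bp palindromic recombination site.
LOXPSYM = Motif("loxPsym", "ATAACTTCGTATAATGTACATTATACGAAGTTAT")


@dataclass(frozen=True)
class LoxUnit:
    """One inter-motif segment of a chromosome."""

    index: int
    sequence: str

    @property
    def id(self) -> str:
        return f"LU{self.index}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_zero_length(self) -> bool:
        """Adjacent motif copies produce a legal, zero-length LU."""
        return len(self.sequence) == 0


def _find_all(haystack: str, needle: str) -> list[int]:
    # all (possibly overlapping) start positions
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_motifs(sequence: str, motif: Motif, topology: str = "linear") -> list[tuple[int, int]]:
    """Locate every occurrence of ``motif`` in ``sequence``.

    Both strands are scanned; for a palindromic motif the reverse-strand scan
    cannot produce a second report of the same interval. Overlapping
    occurrences are resolved leftmost-greedy. For circular topology the
    doubled sequence is scanned so origin-spanning occurrences are found;
    positions are reported mod length and deduplicated.

    Returns
    -------
    list of (start, end)
        Sorted, non-overlapping 0-based half-open intervals.
    """
    _check_topology(topology)
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    m = len(motif)
    if m > len(seq):
        raise ValueError("motif longer than sequence")

    needles = {motif.sequence}
    needles.add(revcomp(motif.sequence))  # a single element if palindromic

    if topology == "circular":
        scanned = seq + seq[: m - 1]
    else:
        scanned = seq

    starts: set[int] = set()
    for needle in needles:
        for pos in _find_all(scanned, needle):
            starts.add(pos % len(seq) if topology == "circular" else pos)

    # leftmost-greedy overlap resolution (mod-length aware for circular)
    sites: list[tuple[int, int]] = []
    last_end = -1
    for s in sorted(starts):
        if s < last_end:
            continue
        sites.append((s, s + m))
        last_end = s + m
    if topology == "circular" and len(sites) > 1:
        # the last site may wrap and collide with the first
        s, e = sites[-1]
        if e > len(seq) and (e - len(seq)) > sites[0][0]:
            sites.pop()
    return sites


def segment(sequence: str, motif_sites: list[tuple[int, int]], topology: str = "linear") -> list[LoxUnit]:
    """Cut a chromosome into LUs at its motif sites.

    Linear: ``LU_0 = [0, start_0)``, ``LU_k = [end_{k-1}, start_k)``,
    ``LU_n = [end_{n-1}, len)``. Circular: ``LU_k = [end_k, start_{k+1 mod n})``
    with wraparound; at least one site is required.
    """
    _check_topology(topology)
    seq = sequence.upper()
    n = len(motif_sites)
    if topology == "circular":
        if n == 0:
            raise ValueError("circular segmentation requires at least one motif site")
        lus = []
        for k in range(n):
            lo = motif_sites[k][1]
            hi = motif_sites[(k + 1) % n][0]
            if k < n - 1:
                lus.append(LoxUnit(k, seq[lo:hi]))
            else:  # wraps through the origin
                lus.append(LoxUnit(k, seq[lo:] + seq[:hi]))
        return lus
    lus = [LoxUnit(0, seq[: motif_sites[0][0]] if n else seq)]
    for k in range(1, n):
        lus.append(LoxUnit(k, seq[motif_sites[k - 1][1]: motif_sites[k][0]]))
    if n:
        lus.append(LoxUnit(n, seq[motif_sites[n - 1][1]:]))
    return lus


@dataclass
class AnnotatedChromosome:
    """A chromosome plus its motif annotation and LU segmentation."""

    name: str
    sequence: str
    topology: str
    motif: Motif
    motif_sites: list[tuple[int, int]]
    lus: list[LoxUnit]

    @classmethod
    def annotate(cls, name: str, sequence: str, motif: Motif = LOXPSYM,
                 topology: str = "linear") -> "AnnotatedChromosome":
        """Scan + segment in one step. Input is uppercased; Ns are tolerated
        in the chromosome (they can never match a motif)."""
        seq = sequence.upper()
        sites = scan_motifs(seq, motif, topology)
        lus = segment(seq, sites, topology)
        chrom = cls(name, seq, topology, motif, sites, lus)
        chrom.validate()
        return chrom

    def validate(self) -> None:
        m = len(self.motif)
        L = len(self.sequence)
        prev_end = -1
        for (s, e) in self.motif_sites:
            if e - s != m:
                raise ValueError(f"{self.name}: motif site ({s},{e}) has wrong length")
            if s < prev_end:
                raise ValueError(f"{self.name}: motif sites overlap at {s}")
            sub = self.sequence[s:e] if e <= L else self.sequence[s:] + self.sequence[: e - L]
            if sub != self.motif.sequence:
                raise ValueError(f"{self.name}: sequence at ({s},{e}) is not the motif")
            prev_end = e
        n = len(self.motif_sites)
        expected = n if self.topology == "circular" else n + 1
        if len(self.lus) != expected:
            raise ValueError(f"{self.name}: expected {expected} LUs, got {len(self.lus)}")

    @property
    def n_junctions(self) -> int:
        return len(self.motif_sites)

    def lu_by_id(self, lu_id: str) -> LoxUnit:
        try:
            return self.lus[int(lu_id[2:])]
        except (ValueError, IndexError):
            raise KeyError(f"unknown LU id {lu_id!r} on {self.name}")

    def lu_intervals(self) -> list[tuple[str, int, int]]:
        """(id, start, end) per LU; for circular, the wraparound LU's end
        exceeds the sequence length (end = start + LU length)."""
        out = []
        if self.topology == "circular":
            n = len(self.motif_sites)
            for k, lu in enumerate(self.lus):
                lo = self.motif_sites[k][1]
                out.append((lu.id, lo, lo + lu.length))
        else:
            pos = 0
            for k, lu in enumerate(self.lus):
                out.append((lu.id, pos, pos + lu.length))
                if k < len(self.motif_sites):
                    pos = self.motif_sites[k][1]
        return out


@dataclass
class LUArrangement:
    """An ordered, signed list of LU references — the genotype at LU
    granularity. ``units`` holds ``(lu_id, orientation)`` with orientation
    ``"+"`` or ``"-"``; ids may repeat (duplication) or be absent (deletion).
    """

    topology: str
    units: list[tuple[str, str]]
    source: str

    def __post_init__(self):
        _check_topology(self.topology)
        for lu_id, sign in self.units:
            if sign not in ("+", "-"):
                raise ValueError(f"orientation must be '+' or '-', got {sign!r}")

    @classmethod
    def identity(cls, reference: AnnotatedChromosome) -> "LUArrangement":
        return cls(reference.topology, [(lu.id, "+") for lu in reference.lus], reference.name)

    def lu_ids(self) -> list[str]:
        return [u for u, _ in self.units]

    def __len__(self) -> int:
        return len(self.units)


def render(arrangement: LUArrangement, reference: AnnotatedChromosome) -> str:
    """Realize an arrangement as a DNA string.

    LU sequences are concatenated in order (reverse-complemented when
    orientation is ``-``) with one motif copy between consecutive LUs; a
    circular arrangement also gets the closing motif between last and first
    LU. Rendering of a circular arrangement starts at its first unit, so the
    identity render equals the reference up to rotation.
    """
    if not arrangement.units:
        raise ValueError("cannot render an empty arrangement")
    motif = reference.motif.sequence
    parts = []
    for lu_id, sign in arrangement.units:
        lu = reference.lu_by_id(lu_id)
        parts.append(lu.sequence if sign == "+" else revcomp(lu.sequence))
    body = motif.join(parts)
    if arrangement.topology == "circular":
        body += motif
    return body


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)]) if length else ""


def generate_fixture(n_lus: int, lu_length_range: tuple[int, int], motif: Motif = LOXPSYM,
                     topology: str = "linear", gc: float = 0.40, seed: int = 0,
                     name: str | None = None) -> AnnotatedChromosome:
    """Generate a synthetic chromosome fixture: ``n_lus`` random-DNA LUs
    separated by single motif copies.

    Deterministic for a fixed seed. LU sequences are rejection-sampled so no
    spurious motif occurrence is created (checked again on the assembled
    sequence, including junctions).
    """
    _check_topology(topology)
    lo, hi = lu_length_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid LU length range ({lo}, {hi})")
    min_lus = 1 if topology == "circular" else 2
    if n_lus < min_lus:
        raise ValueError(f"{topology} fixture needs at least {min_lus} LUs, got {n_lus}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")

    rng = np.random.default_rng(seed)
    rc = revcomp(motif.sequence)
    for attempt in range(50):
        lus = []
        ok = True
        for _ in range(n_lus):
            length = int(rng.integers(lo, hi + 1))
            for _retry in range(100):
                s = _random_dna(rng, length, gc)
                if motif.sequence not in s and rc not in s:
                    break
            else:
                raise ValueError("could not sample a motif-free LU; parameters infeasible")
            lus.append(s)
        if topology == "circular":
            seq = "".join(motif.sequence + lu for lu in lus)
        else:
            seq = motif.sequence.join(lus)
        expected = n_lus if topology == "circular" else n_lus - 1
        if len(scan_motifs(seq, motif, topology)) == expected:
            break
        ok = False
    if not ok:  # pragma: no cover - junction artifacts are astronomically rare
        raise ValueError("fixture assembly kept creating spurious motif occurrences")
    if name is None:
        name = f"fixture_{topology}_{n_lus}lu_seed{seed}"
    return AnnotatedChromosome.annotate(name, seq, motif, topology)
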