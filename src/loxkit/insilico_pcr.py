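"""Mismatch-tolerant in-silico end-point PCR.

Predicts amplicons for a primer panel against query sequences (for example
long-read assemblies, whose residual errors are absorbed by the per-primer
mismatch allowance) and reduces them to a binary presence/absence genotype
matrix: one row per sample, one column per junction in reference order,
1 if at least one amplicon of acceptable size can form, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import revcomp
from .tag_design import TagPanel, _encode, _hamming_hits

__all__ = [
    "AmpliconCall",
    "GenotypeMatrix",
    "find_primer_sites",
    "predict_amplicons",
    "genotype",
]

DEFAULT_MAX_AMPLICON = 1000
DEFAULT_MAX_MISMATCH = 2


@dataclass
class AmpliconCall:
    sample: str
    junction_id: str
    present: int
    # (start, end, strand, mm_fwd, mm_rev); end may exceed the sequence
    # length for amplicons crossing a circular origin
    amplicons: list[tuple[int, int, str, int, int]] = field(default_factory=list)


def find_primer_sites(query: str, primer: str, max_mismatch: int,
                      topology: str = "linear") -> list[tuple[int, str, int]]:
    """All (pos, strand, mismatches) where the primer binds the query with at
    most ``max_mismatch`` substitutions, on either strand.

    ``pos`` is the 0-based start of the matched window on the forward strand.
    Circular queries are scanned on the doubled sequence; positions are
    reported mod length and deduplicated.
    """
    if len(primer) > len(query):
        raise ValueError("primer longer than query")
    seq = query.upper()
    L = len(seq)
    scanned = seq + seq[: len(primer) - 1] if topology == "circular" else seq
    enc = _encode(scanned)
    hits: dict[tuple[int, str], int] = {}
    for strand, needle in (("+", primer.upper()), ("-", revcomp(primer.upper()))):
        pos, mm = _hamming_hits(enc, needle, max_mismatch)
        for p, m in zip(pos, mm):
            key = (int(p) % L if topology == "circular" else int(p), strand)
            if key not in hits or m < hits[key]:
                hits[key] = int(m)
    return sorted((p, s, m) for (p, s), m in hits.items())


def predict_amplicons(query: str, pair, max_amplicon: int = DEFAULT_MAX_AMPLICON,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      topology: str = "linear", sample: str = "") -> AmpliconCall:
    """Enumerate every amplicon the pair can form on the query.

    An amplicon is any forward hit on one strand combined with a reverse hit
    on the opposite strand, downstream in amplifiable orientation, with total
    product length <= ``max_amplicon``. Detection is strand-symmetric: the
    reverse-complemented query yields the same presence value.
    """
    if not pair.fwd_seq or not pair.rev_seq:
        raise ValueError("primer pair has an empty primer sequence")
    kf, kr = len(pair.fwd_seq), len(pair.rev_seq)
    if max_amplicon < kf + kr:
        raise ValueError(f"max_amplicon {max_amplicon} smaller than combined primer length {kf + kr}")
    fwd_hits = find_primer_sites(query, pair.fwd_seq, max_mismatch, topology)
    rev_hits = find_primer_sites(query, pair.rev_seq, max_mismatch, topology)
    L = len(query)
    circular = topology == "circular"

    amplicons = []
    # (left primer hits, right primer hits, reported strand, left len, right len)
    combos = (
        ([h for h in fwd_hits if h[1] == "+"], [h for h in rev_hits if h[1] == "-"], "+", kf, kr, True),
        ([h for h in rev_hits if h[1] == "+"], [h for h in fwd_hits if h[1] == "-"], "-", kr, kf, False),
    )
    for lefts, rights, strand, klen_l, klen_r, fwd_is_left in combos:
        for (pl, _, ml) in lefts:
            for (pr, _, mr) in rights:
                if circular:
                    dist = (pr + klen_r - pl) % L
                    if dist == 0:
                        dist = L
                else:
                    dist = pr + klen_r - pl
                if dist < max(klen_l, klen_r) or dist > max_amplicon:
                    continue
                if not circular and pr < pl:
                    continue
                mm_f, mm_r = (ml, mr) if fwd_is_left else (mr, ml)
                amplicons.append((pl, pl + dist, strand, mm_f, mm_r))
    amplicons.sort()
    return AmpliconCall(sample=sample, junction_id=pair.junction_id,
                        present=1 if amplicons else 0, amplicons=amplicons)


@dataclass
class GenotypeMatrix:
    """Binary presence calls: rows = samples, columns = junction ids in the
    panel's reference order."""

    df: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def junctions(self) -> list[str]:
        return list(self.df.columns)

    def row(self, sample: str) -> list[int]:
        return [int(v) for v in self.df.loc[sample]]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        df.columns = [str(c) for c in df.columns]
        return cls(df.astype(int))

    def plot_heatmap(self, path, present_color: str = "0.55", absent_color: str = "white") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        fig, ax = plt.subplots(
            figsize=(max(4, 0.28 * len(self.junctions)), max(2, 0.35 * len(self.samples))))
        ax.imshow(self.df.to_numpy(), cmap=ListedColormap([absent_color, present_color]),
                  vmin=0, vmax=1, aspect="auto", interpolation="none")
        ax.set_xticks(range(len(self.junctions)), self.junctions, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.samples)), self.samples, fontsize=7)
        ax.set_xlabel("junction")
        ax.set_ylabel("sample")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def genotype(samples: list[tuple[str, str]] | dict[str, str], panel: TagPanel,
             max_amplicon: int = DEFAULT_MAX_AMPLICON,
             max_mismatch: int = DEFAULT_MAX_MISMATCH,
             topology: str | dict[str, str] = "linear",
             collect_calls: bool = False):
    """Genotype every sample against every panel pair.

    Parameters
    ----------
    samples : list of (name, sequence) or dict
    topology : str or per-sample dict
    collect_calls : bool
        When True, also return the full per-cell :class:`AmpliconCall` list.

    Returns
    -------
    GenotypeMatrix, or (GenotypeMatrix, list[AmpliconCall])
    """
    if isinstance(samples, dict):
        samples = list(samples.items())
    names = [n for n, _ in samples]
    if len(names) != len(set(names)):
        raise ValueError("duplicate sample names")
    if not panel.pairs:
        raise ValueError("empty primer panel")

    def topo(name):
        return topology.get(name, "linear") if isinstance(topology, dict) else topology

    rows = {}
    calls = []
    for name, seq in samples:
        row = []
        for pair in panel.pairs:
            call = predict_amplicons(seq, pair, max_amplicon, max_mismatch, topo(name), sample=name)
            row.append(call.present)
            if collect_calls:
                calls.append(call)
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=panel.junction_ids()).astype(int)
    matrix = GenotypeMatrix(df)
    return (matrix, calls) if collect_calls else matrix
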