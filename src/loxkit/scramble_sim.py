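"""Cre-mediated rearrangement simulator on signed LU arrangements.

Events act on whole LUs (inter-motif recombination): deletion, inversion,
duplication, and translocation of a contiguous block. The sampler draws
event kinds from a configurable mix, block extents geometrically, and
targets uniformly, rejecting draws that violate viability (a protected-LU
set standing in for, e.g., the centromere unit). Every run emits an ordered
truth log sufficient to replay the final arrangement exactly.

Randomness contract: a master seed; per-isolate substreams are spawned via
``numpy.random.SeedSequence(master).spawn(n)``, so logs are portable and
populations reproducible isolate-by-isolate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genome_model import AnnotatedChromosome, LUArrangement, render

__all__ = [
    "RecombinationEvent",
    "SimConfig",
    "SimulationError",
    "apply_event",
    "sample_events",
    "replay",
    "simulate_population",
]

EVENT_KINDS = ("deletion", "inversion", "duplication", "translocation")

#: Default event mix: observed circular-chromosome proportions — deletions
#: 63%, inversions 23%, the remaining 14% split evenly between the two
#: complex kinds.
DEFAULT_EVENT_MIX = {"deletion": 0.63, "inversion": 0.23,
                     "duplication": 0.07, "translocation": 0.07}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RecombinationEvent:
    """One event on the *current* arrangement: ``lu_span=(i, j)`` is a
    contiguous, inclusive block of positions; ``target_pos`` (duplication /
    translocation) is an insertion index in the pre-event arrangement and
    must lie outside ``[i, j+1]`` for translocations."""

    kind: str
    lu_span: tuple[int, int]
    target_pos: int | None = None
    target_orientation: str = "+"

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.target_orientation not in ("+", "-"):
            raise ValueError("target_orientation must be '+' or '-'")


@dataclass
class SimConfig:
    event_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    n_events: dict = field(default_factory=lambda: {"poisson": 3.0})
    protected_lus: set = field(default_factory=set)
    seed: int = 0
    block_len_mean: float = 2.0
    max_retries: int = 100

    def __post_init__(self):
        self.protected_lus = set(self.protected_lus)
        total = sum(self.event_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"event_mix must sum to 1, got {total}")
        for k in self.event_mix:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind in mix: {k!r}")
        if not ({"fixed", "poisson"} & set(self.n_events)):
            raise ValueError("n_events needs a 'fixed' or 'poisson' entry")
        if self.block_len_mean < 1.0:
            raise ValueError("block_len_mean must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("n_isolates", None)  # population-level key, not sampler config
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protected_lus"] = sorted(self.protected_lus)
        return d


def _flip(block: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(lu, "-" if s == "+" else "+") for lu, s in reversed(block)]


def apply_event(arrangement: LUArrangement, event: RecombinationEvent,
                protected_lus: set | frozenset = frozenset()) -> LUArrangement:
    """Apply one recombination event, returning a new arrangement.

    Deletion removes the block (never a protected LU, never the whole
    arrangement); inversion reverses block order and flips every sign;
    duplication inserts a block copy at ``target_pos`` (default tandem:
    just after the block, same orientation); translocation removes the block
    and reinserts it at ``target_pos`` (an index of the pre-event
    arrangement, outside the block).
    """
    units = list(arrangement.units)
    i, j = event.lu_span
    if not (0 <= i <= j < len(units)):
        raise ValueError(f"lu_span ({i}, {j}) out of range for arrangement of length {len(units)}")
    block = units[i: j + 1]

    if event.kind == "deletion":
        hit = {lu for lu, _ in block} & set(protected_lus)
        if hit:
            raise SimulationError(f"deletion would remove protected LU(s): {sorted(hit)}")
        if j - i + 1 == len(units):
            raise SimulationError("deletion would empty the arrangement")
        new = units[:i] + units[j + 1:]
    elif event.kind == "inversion":
        new = units[:i] + _flip(block) + units[j + 1:]
    elif event.kind == "duplication":
        t = event.target_pos if event.target_pos is not None else j + 1
        if not 0 <= t <= len(units):
            raise ValueError(f"duplication target_pos {t} out of range")
        copy = block if event.target_orientation == "+" else _flip(block)
        new = units[:t] + copy + units[t:]
    else:  # translocation
        t = event.target_pos
        if t is None:
            raise ValueError("translocation requires target_pos")
        if i <= t <= j + 1:
            raise ValueError(f"translocation target_pos {t} inside the moved block [{i}, {j}]")
        if not 0 <= t <= len(units):
            raise ValueError(f"translocation target_pos {t} out of range")
        moved = block if event.target_orientation == "+" else _flip(block)
        rest = units[:i] + units[j + 1:]
        t_adj = t if t < i else t - (j - i + 1)
        new = rest[:t_adj] + moved + rest[t_adj:]
    return LUArrangement(arrangement.topology, new, arrangement.source)


def _log_entry(event: RecombinationEvent, arrangement: LUArrangement) -> dict:
    i, j = event.lu_span
    return {
        "kind": event.kind,
        "lu_span": [i, j],
        "lu_ids": [lu for lu, _ in arrangement.units[i: j + 1]],
        "target_pos": event.target_pos,
        "target_orientation": event.target_orientation,
    }


def sample_events(arrangement: LUArrangement, config: SimConfig,
                  rng: np.random.Generator | None = None):
    """Draw and apply a random event series.

    Returns ``(final_arrangement, log)`` where ``log`` is an ordered list of
    JSON-ready event records; replaying it with :func:`replay` reproduces the
    final arrangement exactly. Draws violating viability are rejected and
    redrawn up to ``config.max_retries`` times per event.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if "fixed" in config.n_events:
        n = int(config.n_events["fixed"])
    else:
        n = int(rng.poisson(float(config.n_events["poisson"])))

    kinds = sorted(config.event_mix)
    probs = np.array([config.event_mix[k] for k in kinds])
    current = arrangement
    log: list[dict] = []
    p_geom = min(1.0, 1.0 / config.block_len_mean)
    for _ in range(n):
        last_err = None
        for _attempt in range(config.max_retries):
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            size = len(current)
            blen = min(int(rng.geometric(p_geom)), size)
            i = int(rng.integers(0, size - blen + 1))
            j = i + blen - 1
            target_pos = None
            orientation = "+"
            if kind in ("duplication", "translocation"):
                orientation = "+" if rng.integers(2) == 0 else "-"
                if kind == "duplication":
                    target_pos = int(rng.integers(0, size + 1))
                else:
                    valid = list(range(0, i)) + list(range(j + 2, size + 1))
                    if not valid:
                        last_err = "no valid translocation target (block spans the arrangement)"
                        continue
                    target_pos = int(valid[int(rng.integers(0, len(valid)))])
            event = RecombinationEvent(kind, (i, j), target_pos, orientation)
            try:
                nxt = apply_event(current, event, config.protected_lus)
            except SimulationError as exc:
                last_err = str(exc)
                continue
            log.append(_log_entry(event, current))
            current = nxt
            break
        else:
            raise SimulationError(
                f"retry budget ({config.max_retries}) exhausted; last constraint: {last_err}")
    return current, log


def replay(arrangement: LUArrangement, log: list[dict]) -> LUArrangement:
    """Re-apply a truth log to the starting arrangement."""
    current = arrangement
    for rec in log:
        event = RecombinationEvent(rec["kind"], tuple(rec["lu_span"]),
                                   rec.get("target_pos"), rec.get("target_orientation") or "+")
        current = apply_event(current, event)
    return current


def simulate_population(reference: AnnotatedChromosome, n_isolates: int, config: SimConfig):
    """Simulate ``n_isolates`` independent isolates from one reference.

    Returns a list of records
    ``{"name", "topology", "events", "final_units", "sequence"}``; the
    rendered sequence always equals ``render(replay(events))``.
    """
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    start = LUArrangement.identity(reference)
    streams = np.random.SeedSequence(config.seed).spawn(n_isolates)
    records = []
    for idx in range(n_isolates):
        rng = np.random.default_rng(streams[idx])
        final, log = sample_events(start, config, rng=rng)
        records.append({
            "name": f"iso{idx + 1:04d}",
            "topology": final.topology,
            "events": log,
            "final_units": [[lu, s] for lu, s in final.units],
            "sequence": render(final, reference),
        })
    return records


def write_truth_logs(records: list[dict], path) -> None:
    """JSON truth logs for a population (sequences omitted — they live in
    the FASTA)."""
    slim = [{k: v for k, v in rec.items() if k != "sequence"} for rec in records]
    with open(path, "w") as fh:
        json.dump(slim, fh, indent=1)


def read_truth_logs(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
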