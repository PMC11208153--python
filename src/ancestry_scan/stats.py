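"""Interval-overlap permutation testing, presence/absence pattern counting,
and the fixed-rounding summary arithmetic used in reports."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .genome_io import Genome, Interval, overlap_bases


class PlacementError(RuntimeError):
    """Random interval placement failed."""


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: List[float]
    p_value: float
    seed: int
    stat: str = "bases"


def _shuffle_intervals(
    intervals: Sequence[Interval],
    genome: Genome,
    rng: np.random.Generator,
    max_attempts: int = 1_000,
) -> List[Interval]:
    """Re-place every interval uniformly at random on its own sequence,
    preserving length, rejection-sampling until the placed set is mutually
    non-overlapping."""
    placed: Dict[str, List[Tuple[int, int]]] = {}
    out: List[Interval] = []
    for iv in intervals:
        seq_len = genome.lengths.get(iv.seq_name)
        if seq_len is None:
            raise PlacementError(f"sequence {iv.seq_name!r} not in genome")
        width = iv.width
        if width > seq_len:
            raise PlacementError(
                f"interval of {width} bases cannot be placed on {iv.seq_name} ({seq_len} bases)"
            )
        existing = placed.setdefault(iv.seq_name, [])
        for _ in range(max_attempts):
            start = int(rng.integers(0, seq_len - width + 1))
            end = start + width
            if all(end <= s or start >= e for s, e in existing):
                existing.append((start, end))
                out.append(Interval(iv.seq_name, start, end))
                break
        else:
            raise PlacementError(
                f"could not place a {width}-base interval on {iv.seq_name} in "
                f"{max_attempts} attempts; the genome may be too crowded"
            )
    return out


def _overlap_stat(a: Sequence[Interval], b: Sequence[Interval], stat: str) -> float:
    if stat == "bases":
        return float(overlap_bases(a, b))
    if stat == "blocks":
        by_seq: Dict[str, List[Interval]] = {}
        for iv in b:
            by_seq.setdefault(iv.seq_name, []).append(iv)
        n = 0
        for iv in a:
            if any(iv.start < jv.end and jv.start < iv.end for jv in by_seq.get(iv.seq_name, ())):
                n += 1
        return float(n)
    raise ValueError(f"unknown statistic {stat!r}")


def permutation_overlap_test(
    set_a: Sequence[Interval],
    set_b: Sequence[Interval],
    genome: Genome,
    n_perm: int = 10_000,
    seed: int = 0,
    stat: str = "bases",
) -> PermutationResult:
    """Permutation test for overlap enrichment of interval set A with B.

    The null re-places every A interval uniformly at random on its own
    sequence (length preserved, placements mutually non-overlapping). The
    p-value uses the add-one estimator (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm >= 1 required")
    set_a = list(set_a)
    set_b = list(set_b)
    observed = _overlap_stat(set_a, set_b, stat)
    rng = np.random.default_rng(seed)
    null_stats: List[float] = []
    exceed = 0
    for _ in range(n_perm):
        shuffled = _shuffle_intervals(set_a, genome, rng)
        s = _overlap_stat(shuffled, set_b, stat)
        null_stats.append(s)
        if s >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed_stat=observed, null_stats=null_stats, p_value=p, seed=seed, stat=stat
    )


# ---------------------------------------------------------------------------
# presence/absence patterns


@dataclass
class PAVMatrix:
    """Orthogroup presence flags over an ordered list of genomes."""

    genome_ids: List[str]
    presence: Dict[str, Tuple[bool, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genome_ids) < 2:
            raise ValueError("PAV analysis needs >= 2 genomes")
        for og, flags in self.presence.items():
            if len(flags) != len(self.genome_ids):
                raise ValueError(f"orthogroup {og!r}: flag count != genome count")
            if not any(flags):
                raise ValueError(f"orthogroup {og!r} absent from every genome")

    def pattern(self, orthogroup: str) -> str:
        return "".join("1" if f else "0" for f in self.presence[orthogroup])


def read_pav_matrix(path) -> PAVMatrix:
    """Tab-separated file: header of genome ids; rows of orthogroup id + 0/1."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genome_ids = header[1:]
        presence: Dict[str, Tuple[bool, ...]] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            presence[cols[0]] = tuple(c not in ("0", "") for c in cols[1:])
    return PAVMatrix(genome_ids=genome_ids, presence=presence)


@dataclass
class PAVPatternCounts:
    pattern_counts: Dict[str, int]
    private_counts: Dict[str, int]
    shared_all: int
    total: int


def pav_patterns(matrix: PAVMatrix) -> PAVPatternCounts:
    """Count observed presence patterns, per-genome private orthogroups, and
    the all-present class."""
    pattern_counts: Dict[str, int] = {}
    for og in matrix.presence:
        pat = matrix.pattern(og)
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1
    n = len(matrix.genome_ids)
    private_counts = {}
    for i, gid in enumerate(matrix.genome_ids):
        pat = "".join("1" if j == i else "0" for j in range(n))
        private_counts[gid] = pattern_counts.get(pat, 0)
    shared_all = pattern_counts.get("1" * n, 0)
    return PAVPatternCounts(
        pattern_counts=pattern_counts,
        private_counts=private_counts,
        shared_all=shared_all,
        total=len(matrix.presence),
    )


# ---------------------------------------------------------------------------
# summary arithmetic (fixed rounding conventions)


def _round_half_up(x: float, decimals: int = 0) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def percent(part: float, whole: float) -> float:
    """100*part/whole, rounded half-up to one decimal."""
    if whole == 0:
        raise ZeroDivisionError("percent: zero denominator")
    return _round_half_up(100.0 * part / whole, 1)


def ratio(a: float, b: float) -> float:
    """a/b rounded half-up to one decimal."""
    if b == 0:
        raise ZeroDivisionError("ratio: zero denominator")
    return _round_half_up(a / b, 1)


def fold(a: float, b: float) -> int:
    """a/b rounded half-up to the nearest integer."""
    if b == 0:
        raise ZeroDivisionError("fold: zero denominator")
    return int(_round_half_up(a / b, 0))


def rate_per_unit_trunc(count: float, units: float) -> float:
    """count/units truncated (not rounded) to one decimal."""
    if units == 0:
        raise ZeroDivisionError("rate_per_unit_trunc: zero denominator")
    return math.floor(10.0 * count / units) / 10.0


def mean_per_group_trunc(total: float, n_groups: float) -> int:
    """total/n_groups truncated to an integer."""
    if n_groups == 0:
        raise ZeroDivisionError("mean_per_group_trunc: zero denominator")
    return int(total // n_groups)


def summary_report(values: Dict[str, Tuple]) -> Dict[str, Union[float, int]]:
    """Apply a named rule to each (rule, *args) input.

    ``values`` maps output name -> (rule_name, arg1, arg2); rules are
    percent, ratio, fold, rate_per_unit_trunc and mean_per_group_trunc."""
    rules = {
        "percent": percent,
        "ratio": ratio,
        "fold": fold,
        "rate_per_unit_trunc": rate_per_unit_trunc,
        "mean_per_group_trunc": mean_per_group_trunc,
    }
    out: Dict[str, Union[float, int]] = {}
    for name, (rule, *args) in values.items():
        out[name] = rules[rule](*args)
    return out
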