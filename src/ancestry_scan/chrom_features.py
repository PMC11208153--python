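"""Chromosome-scale features: diagnostic-kmer centromeres, telomeres, and
hierarchical base-composition profiles."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import _seqcodes as sc
from .genome_io import Genome, Interval, merge_intervals

TELOMERE_MOTIFS = ("CCCGAAA", "CCCTAAA", "TTTCGGG", "TTTAGGG")


class CalibrationError(ValueError):
    """Raised when a density-threshold calibration is impossible."""


@dataclass
class DiagnosticKmerSet:
    """Canonical k-mers abundant inside known centromeric regions and absent
    everywhere else."""

    k: int = 25
    kmers: Set[int] = field(default_factory=set)  # canonical 2-bit codes
    min_centromere_count: int = 25

    def __len__(self) -> int:
        return len(self.kmers)

    def kmer_strings(self) -> List[str]:
        return sorted(_code_to_string(c, self.k) for c in self.kmers)


def _code_to_string(code: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(bases[(code >> shift) & 3])
    return "".join(out)


def canonical_code(kmer: str) -> int:
    codes = sc.encode(kmer)
    if (codes >= 4).any():
        raise ValueError("kmer contains non-ACGT characters")
    fwd = int(sc.kmer_codes(codes, len(kmer))[0])
    rev = int(sc.kmer_codes(sc.revcomp_codes(codes), len(kmer))[0])
    return min(fwd, rev)


@dataclass
class DensityProfile:
    """Per-sequence diagnostic-kmer coverage over overlapping blocks."""

    block: int = 250_000
    step: int = 50_000
    # per sequence: (block starts, block widths, coverage fractions)
    profiles: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class CompositionLayers:
    """Annotation layers; priority exon > ty3 > other_repeat > intron > other."""

    exon: List[Interval] = field(default_factory=list)
    ty3: List[Interval] = field(default_factory=list)
    other_repeat: List[Interval] = field(default_factory=list)
    intron: List[Interval] = field(default_factory=list)


COMPOSITION_CLASSES = ("exon", "ty3", "other_repeat", "intron", "other")


def extract_diagnostic_kmers(
    genome: Genome,
    centromere_regions: Sequence[Interval],
    k: int = 25,
    min_count: int = 25,
) -> DiagnosticKmerSet:
    """Canonical k-mers occurring >= ``min_count`` times inside the union of
    the given regions and zero times outside it. K-mers covering an N are
    never counted. A k-mer occurrence straddling a region boundary counts as
    outside."""
    if not centromere_regions:
        return DiagnosticKmerSet(k=k, kmers=set(), min_centromere_count=min_count)
    regions = merge_intervals(centromere_regions)
    by_seq: Dict[str, List[Interval]] = {}
    for iv in regions:
        iv.bound_check(genome)
        by_seq.setdefault(iv.seq_name, []).append(iv)

    inside_parts: List[np.ndarray] = []
    outside_parts: List[np.ndarray] = []
    for name, seq in genome.sequences.items():
        codes = sc.encode(seq)
        kcodes = sc.canonical_kmer_codes(codes, k)
        if kcodes.size == 0:
            continue
        inside = np.zeros(kcodes.size, dtype=bool)
        for iv in by_seq.get(name, ()):  # occurrence fully inside the region
            lo, hi = iv.start, iv.end - k + 1
            if hi > lo:
                inside[lo:hi] = True
        valid = kcodes != sc.POISON
        inside_parts.append(kcodes[inside & valid])
        outside_parts.append(kcodes[~inside & valid])

    if not inside_parts:
        return DiagnosticKmerSet(k=k, kmers=set(), min_centromere_count=min_count)
    inside_codes = np.concatenate(inside_parts)
    uniq, counts = np.unique(inside_codes, return_counts=True)
    candidates = uniq[counts >= min_count]
    if candidates.size and outside_parts:
        outside_codes = np.unique(np.concatenate(outside_parts))
        candidates = candidates[~np.isin(candidates, outside_codes)]
    return DiagnosticKmerSet(k=k, kmers=set(int(c) for c in candidates), min_centromere_count=min_count)


def kmer_coverage_mask(seq: str, kmers: DiagnosticKmerSet) -> np.ndarray:
    """Boolean per-base array: covered by >= 1 diagnostic-kmer occurrence
    (union of [pos, pos+k) spans over both strands)."""
    codes = sc.encode(seq)
    kcodes = sc.canonical_kmer_codes(codes, kmers.k)
    covered = np.zeros(len(seq), dtype=bool)
    if kcodes.size == 0 or not kmers.kmers:
        return covered
    kset = np.fromiter(kmers.kmers, dtype=np.uint64)
    kset.sort()
    pos = np.flatnonzero(_in_sorted(kcodes, kset))
    if pos.size == 0:
        return covered
    # union of [p, p+k) via a difference array
    diff = np.zeros(len(seq) + 1, dtype=np.int64)
    np.add.at(diff, pos, 1)
    np.add.at(diff, np.minimum(pos + kmers.k, len(seq)), -1)
    return np.cumsum(diff[:-1]) > 0


def _in_sorted(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(sorted_set, values)
    idx[idx == sorted_set.size] = 0
    return sorted_set[idx] == values if sorted_set.size else np.zeros(values.size, dtype=bool)


def kmer_density_scan(
    genome: Genome,
    kmers: DiagnosticKmerSet,
    block: int = 250_000,
    step: int = 50_000,
) -> DensityProfile:
    """Coverage fraction of diagnostic kmers in overlapping blocks starting
    at multiples of ``step``; the last block may be short and its fraction
    uses the actual width."""
    profile = DensityProfile(block=block, step=step)
    for name, seq in genome.sequences.items():
        covered = kmer_coverage_mask(seq, kmers)
        cum = np.concatenate(([0], np.cumsum(covered)))
        starts = np.arange(0, len(seq), step, dtype=np.int64)
        ends = np.minimum(starts + block, len(seq))
        widths = ends - starts
        fracs = (cum[ends] - cum[starts]) / widths
        profile.profiles[name] = (starts, widths, fracs)
    return profile


def call_centromeres(profile: DensityProfile, threshold: float = 0.0204) -> List[Interval]:
    """Merge all blocks with coverage >= threshold into centromere calls."""
    selected: List[Interval] = []
    for name, (starts, widths, fracs) in profile.profiles.items():
        for s, w, f in zip(starts, widths, fracs):
            if f >= threshold:
                selected.append(Interval(name, int(s), int(s + w)))
    return merge_intervals(selected) if selected else []


def calibrate_threshold(profile: DensityProfile, quantile: float = 5.0) -> float:
    """Threshold = the given percentile (linear interpolation) of the
    per-sequence peak coverage fractions."""
    peaks = []
    for name, (_, _, fracs) in profile.profiles.items():
        if fracs.size:
            peaks.append(float(fracs.max()))
    if len(peaks) < 2:
        raise CalibrationError("calibration needs >= 2 sequences with profiles")
    if max(peaks) == 0.0:
        raise CalibrationError("all-zero density profiles; nothing to calibrate")
    return float(np.percentile(peaks, quantile))


def count_motif_occurrences(seq: str, motif: str) -> int:
    """Overlapping occurrence count of ``motif`` in ``seq``."""
    n = 0
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def find_telomeres(
    genome: Genome,
    motifs: Sequence[str] = TELOMERE_MOTIFS,
    terminal_len: int = 1_000,
    min_copies: int = 10,
) -> Dict[str, Tuple[bool, bool]]:
    """Flag each sequence terminus as telomeric when the listed motifs occur
    at least ``min_copies`` times (overlaps allowed) within its terminal
    ``terminal_len`` bases."""
    out: Dict[str, Tuple[bool, bool]] = {}
    for name, seq in genome.sequences.items():
        tl = min(terminal_len, len(seq))
        head, tail = seq[:tl], seq[-tl:]
        head_n = sum(count_motif_occurrences(head, m) for m in motifs)
        tail_n = sum(count_motif_occurrences(tail, m) for m in motifs)
        out[name] = (head_n >= min_copies, tail_n >= min_copies)
    return out


def composition_class_array(seq_len: int, layers: CompositionLayers, seq_name: str) -> np.ndarray:
    """Per-base class index by priority (0=exon .. 4=other)."""
    arr = np.full(seq_len, 4, dtype=np.uint8)
    # paint lowest priority first so higher priorities overwrite
    for cls_idx, ivs in ((3, layers.intron), (2, layers.other_repeat), (1, layers.ty3), (0, layers.exon)):
        for iv in ivs:
            if iv.seq_name == seq_name:
                arr[iv.start : min(iv.end, seq_len)] = cls_idx
    return arr


def hierarchical_composition(
    genome: Genome,
    layers: CompositionLayers,
    win: int = 5_000_000,
    step: int = 1_000_000,
) -> Tuple[List[Tuple[str, int, int, Dict[str, float]]], Dict[str, float]]:
    """Per-window and whole-genome class fractions under the priority
    exon > ty3 > other_repeat > intron > other.

    Returns (windows, totals) where each window entry is
    (seq_name, start, end, fractions-by-class)."""
    windows_out: List[Tuple[str, int, int, Dict[str, float]]] = []
    total_counts = np.zeros(5, dtype=np.int64)
    for name, seq in genome.sequences.items():
        arr = composition_class_array(len(seq), layers, name)
        total_counts += np.bincount(arr, minlength=5)
        for start in range(0, len(seq), step):
            end = min(start + win, len(seq))
            counts = np.bincount(arr[start:end], minlength=5)
            width = end - start
            fr = {COMPOSITION_CLASSES[i]: counts[i] / width for i in range(5)}
            windows_out.append((name, start, end, fr))
            if end == len(seq):
                break
    total = int(total_counts.sum())
    totals = {COMPOSITION_CLASSES[i]: total_counts[i] / total for i in range(5)}
    return windows_out, totals
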