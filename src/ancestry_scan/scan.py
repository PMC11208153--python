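"""Introgression inference by windowed competitive mapping.

Pipeline stages, each exposed separately and composed by
:func:`run_introgression_scan`:

1. mask low-divergence regions of the recipient reference where recipient
   and donor cannot be discriminated;
2. competitively classify query windows against a concatenated
   recipient+donor reference (per-window labels);
3. call seed blocks (runs of consecutive donor windows);
4. smooth with sliding %donor intervals and classify them;
5. emit final introgressed/ambiguous blocks;
6. optionally project block coordinates through a synteny anchor map.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .genome_io import ConcatRef, Genome, Interval, WindowHit, merge_intervals
from .window_mapper import (
    AlignerConfig,
    FilterConfig,
    TargetIndex,
    WindowSpec,
    align_windows,
    genome_windows,
    make_windows,
)

logger = logging.getLogger(__name__)

LABELS = ("recipient", "donor", "ambiguous", "masked", "unmapped")


@dataclass(frozen=True)
class LowDivConfig:
    interval_len: int = 200_000
    frac_threshold: float = 0.5      # strict >
    identity_threshold: float = 0.98  # strict >
    window_spec: WindowSpec = field(default_factory=lambda: WindowSpec(10_000, 5_000))


@dataclass
class LowDivMask:
    """Sorted, non-overlapping low-divergence intervals on the recipient."""

    intervals: List[Interval] = field(default_factory=list)
    config: LowDivConfig = field(default_factory=LowDivConfig)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals) if self.intervals else []
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}
        for iv in self.intervals:
            self._starts.setdefault(iv.seq_name, []).append(iv.start)
            self._ends.setdefault(iv.seq_name, []).append(iv.end)

    def overlaps(self, seq_name: str, start: int, end: int) -> bool:
        starts = self._starts.get(seq_name)
        if not starts:
            return False
        i = bisect.bisect_right(starts, start) - 1
        if i >= 0 and self._ends[seq_name][i] > start:
            return True
        return i + 1 < len(starts) and starts[i + 1] < end


@dataclass(frozen=True)
class ScanConfig:
    min_run: int = 10
    smooth_n: int = 50
    smooth_overlap: int = 49
    hi_threshold: float = 70.0  # inclusive
    lo_threshold: float = 30.0

    def __post_init__(self) -> None:
        if not self.lo_threshold < self.hi_threshold:
            raise ValueError("lo_threshold < hi_threshold required")
        if not self.smooth_overlap < self.smooth_n:
            raise ValueError("smooth_overlap < smooth_n required")


@dataclass
class AncestryTrack:
    """Per-window ancestry labels along a query genome."""

    genome_id: str
    windows: Dict[str, List[Interval]] = field(default_factory=dict)
    labels: Dict[str, List[str]] = field(default_factory=dict)
    scores: Dict[str, List[Dict[str, int]]] = field(default_factory=dict)

    def label_counts(self) -> Dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for labs in self.labels.values():
            for lab in labs:
                counts[lab] += 1
        return counts

    def n_windows(self) -> int:
        return sum(len(w) for w in self.windows.values())


@dataclass
class SmoothInterval:
    """One sliding %donor interval over the non-masked window sequence."""

    seq_name: str
    first_window: int  # index into the full window list of the sequence
    last_window: int   # inclusive
    filt_start: int    # start index in the non-masked (filtered) sequence
    pct_donor: float


# ---------------------------------------------------------------------------
# low-divergence mask


def low_divergence_mask(
    hits: Iterable[WindowHit],
    recipient: Genome,
    cfg: LowDivConfig = LowDivConfig(),
) -> LowDivMask:
    """Mask recipient intervals where most windows align to the donor at
    high identity.

    The recipient is tiled into consecutive ``interval_len`` bins (last one
    shorter). Windows are assigned to bins by start position; a bin is
    masked iff the fraction of its windows with best-hit identity strictly
    above ``identity_threshold`` strictly exceeds ``frac_threshold``.
    Adjacent masked bins merge.
    """
    spec = cfg.window_spec
    best_identity: Dict[Tuple[str, int], float] = {}
    for h in hits:
        key = (h.query_seq, _window_start(h, spec))
        if h.identity > best_identity.get(key, -1.0):
            best_identity[key] = h.identity
    masked: List[Interval] = []
    for seq_name, length in recipient.lengths.items():
        window_starts = [w.start for w in make_windows(length, spec, seq_name)]
        if not window_starts:
            continue
        n_bins = (length + cfg.interval_len - 1) // cfg.interval_len
        counts = np.zeros(n_bins, dtype=np.int64)
        totals = np.zeros(n_bins, dtype=np.int64)
        for start in window_starts:
            b = start // cfg.interval_len
            totals[b] += 1
            ident = best_identity.get((seq_name, start))
            if ident is not None and ident > cfg.identity_threshold:
                counts[b] += 1
        for b in range(n_bins):
            if totals[b] and counts[b] / totals[b] > cfg.frac_threshold:
                bin_start = b * cfg.interval_len
                masked.append(Interval(seq_name, bin_start, min(bin_start + cfg.interval_len, length)))
    return LowDivMask(intervals=masked, config=cfg)


def _window_start(h: WindowHit, spec: WindowSpec) -> int:
    if h.query_window_index >= 0:
        return h.query_window_index * spec.step
    return (h.qstart // spec.step) * spec.step


# ---------------------------------------------------------------------------
# competitive classification


def competitive_classify(
    hits: Iterable[WindowHit],
    concat: ConcatRef,
    windows: Sequence[Interval],
    mask: Optional[LowDivMask] = None,
    synteny: Optional["SyntenyMap"] = None,
    cfg: FilterConfig = FilterConfig(min_identity=0.99),
    genome_id: str = "query",
) -> AncestryTrack:
    """Label each query window by the origin of its best competitive hit.

    Labels: ``masked`` if the window's recipient-projected span overlaps the
    low-divergence mask (regardless of hits); ``unmapped`` if no hit passes
    the identity/coverage thresholds; ``ambiguous`` if the best recipient
    and donor scores tie exactly; otherwise the origin of the best hit.
    """
    by_window: Dict[Tuple[str, int], Dict[str, int]] = {}
    best_hit: Dict[Tuple[str, int], Dict[str, WindowHit]] = {}
    windows_by_seq: Dict[str, List[Interval]] = {}
    for w in windows:
        windows_by_seq.setdefault(w.seq_name, []).append(w)
    index_of: Dict[Tuple[str, int], int] = {}
    for seq_name, wlist in windows_by_seq.items():
        for i, w in enumerate(wlist):
            index_of[(seq_name, w.start)] = i

    for h in hits:
        if h.query_window_index >= 0:
            key = (h.query_seq, h.query_window_index)
        else:
            idx = index_of.get((h.query_seq, h.qstart))
            if idx is None:
                raise ValueError(
                    f"hit at {h.query_seq}:{h.qstart} does not match any supplied window"
                )
            key = (h.query_seq, idx)
        origin = concat.origin_of(h.target_seq)
        scores = by_window.setdefault(key, {})
        if h.score > scores.get(origin, -1):
            scores[origin] = h.score
            best_hit.setdefault(key, {})[origin] = h

    track = AncestryTrack(genome_id=genome_id)
    for seq_name, wlist in windows_by_seq.items():
        labels: List[str] = []
        sc_list: List[Dict[str, int]] = []
        for i, w in enumerate(wlist):
            scores = by_window.get((seq_name, i), {})
            sc_list.append(dict(scores))
            if mask is not None and _window_masked(w, mask, synteny):
                labels.append("masked")
                continue
            labels.append(_classify_window(scores, best_hit.get((seq_name, i), {}), cfg))
        track.windows[seq_name] = wlist
        track.labels[seq_name] = labels
        track.scores[seq_name] = sc_list
    return track


def _window_masked(w: Interval, mask: LowDivMask, synteny: Optional["SyntenyMap"]) -> bool:
    if synteny is None:
        return mask.overlaps(w.seq_name, w.start, w.end)
    for piece in synteny.project_interval(w):
        if mask.overlaps(piece.seq_name, piece.start, piece.end):
            return True
    return False


def _classify_window(scores: Dict[str, int], hits: Dict[str, WindowHit], cfg: FilterConfig) -> str:
    r, d = scores.get("recipient"), scores.get("donor")
    if r is not None and d is not None and r == d:
        return "ambiguous"
    if r is None and d is None:
        return "unmapped"
    origin = "recipient" if (d is None or (r is not None and r > d)) else "donor"
    best = hits[origin]
    if best.identity >= cfg.min_identity and best.coverage >= cfg.min_coverage:
        return origin
    return "unmapped"


# ---------------------------------------------------------------------------
# block calling


def seed_blocks(track: AncestryTrack, cfg: ScanConfig = ScanConfig()) -> List[Interval]:
    """Maximal runs of >= ``min_run`` consecutive donor-labelled windows.

    Any non-donor label (including masked and unmapped) breaks a run.
    """
    out: List[Interval] = []
    for seq_name, labels in track.labels.items():
        wlist = track.windows[seq_name]
        for s, e in _label_runs(labels, lambda lab: lab == "donor"):
            if e - s >= cfg.min_run:
                out.append(Interval(seq_name, wlist[s].start, wlist[e - 1].end))
    return out


def _label_runs(labels: Sequence[str], pred) -> List[Tuple[int, int]]:
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if pred(lab):
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def percent_donor_intervals(
    track: AncestryTrack, cfg: ScanConfig = ScanConfig()
) -> List[SmoothInterval]:
    """Sliding %donor over the per-sequence run of non-masked windows.

    The denominator is decided windows (donor + recipient) only; intervals
    with no decided window are skipped.
    """
    out: List[SmoothInterval] = []
    for seq_name, labels in track.labels.items():
        keep = [i for i, lab in enumerate(labels) if lab != "masked"]
        if len(keep) < cfg.smooth_n:
            if keep:
                logger.info(
                    "%s: %d non-masked windows < smoothing size %d; no intervals",
                    seq_name, len(keep), cfg.smooth_n,
                )
            continue
        donor = np.array([labels[i] == "donor" for i in keep], dtype=np.int64)
        recip = np.array([labels[i] == "recipient" for i in keep], dtype=np.int64)
        cd = np.concatenate(([0], np.cumsum(donor)))
        cr = np.concatenate(([0], np.cumsum(recip)))
        step = cfg.smooth_n - cfg.smooth_overlap
        for s in range(0, len(keep) - cfg.smooth_n + 1, step):
            e = s + cfg.smooth_n
            nd = int(cd[e] - cd[s])
            nr = int(cr[e] - cr[s])
            if nd + nr == 0:
                continue
            out.append(
                SmoothInterval(
                    seq_name=seq_name,
                    first_window=keep[s],
                    last_window=keep[e - 1],
                    filt_start=s,
                    pct_donor=100.0 * nd / (nd + nr),
                )
            )
    return out


def classify_interval(pct: float, cfg: ScanConfig = ScanConfig()) -> str:
    if pct >= cfg.hi_threshold:
        return "introgressed"
    if pct >= cfg.lo_threshold:
        return "ambiguous"
    return "recipient"


def classify_intervals(
    intervals: Sequence[SmoothInterval], cfg: ScanConfig = ScanConfig()
) -> List[str]:
    return [classify_interval(iv.pct_donor, cfg) for iv in intervals]


def window_smoothed_classes(
    track: AncestryTrack,
    intervals: Sequence[SmoothInterval],
    classes: Sequence[str],
    cfg: ScanConfig = ScanConfig(),
) -> Dict[str, List[Optional[str]]]:
    """Assign every non-masked window the class of the covering smoothing
    interval whose centre is nearest (ties -> the left interval). Windows on
    sequences with no intervals get None."""
    by_seq: Dict[str, List[Tuple[int, str]]] = {}
    for iv, cls in zip(intervals, classes):
        by_seq.setdefault(iv.seq_name, []).append((iv.filt_start, cls))
    out: Dict[str, List[Optional[str]]] = {}
    for seq_name, labels in track.labels.items():
        assigned: List[Optional[str]] = [None] * len(labels)
        pairs = sorted(by_seq.get(seq_name, []))
        if pairs:
            starts = [p[0] for p in pairs]
            keep = [i for i, lab in enumerate(labels) if lab != "masked"]
            half = (cfg.smooth_n - 1) / 2.0
            for j, widx in enumerate(keep):
                # interval centred closest to filtered position j
                target = j - half
                k = bisect.bisect_left(starts, target)
                best = None
                for cand in (k - 1, k):
                    if 0 <= cand < len(starts):
                        s = starts[cand]
                        if s <= j <= s + cfg.smooth_n - 1:  # must cover j
                            dist = abs(s + half - j)
                            if best is None or dist < best[0] - 1e-12:
                                best = (dist, cand)
                if best is None:
                    # j covered by some interval further away (edge windows)
                    for cand, (s, _) in enumerate(pairs):
                        if s <= j <= s + cfg.smooth_n - 1:
                            dist = abs(s + half - j)
                            if best is None or dist < best[0] - 1e-12:
                                best = (dist, cand)
                if best is not None:
                    assigned[widx] = pairs[best[1]][1]
        out[seq_name] = assigned
    return out


def final_blocks(
    track: AncestryTrack,
    intervals: Sequence[SmoothInterval],
    classes: Sequence[str],
    cfg: ScanConfig = ScanConfig(),
) -> List[Interval]:
    """Final introgression calls.

    An introgressed block is a seed run (>= ``min_run`` consecutive donor
    windows) validated by the smoothing: at least one of its windows falls
    in an interval classified introgressed. The block spans the donor run's
    windows. Remaining maximal runs of smoothed-ambiguous windows are
    emitted as ambiguous blocks.
    """
    smoothed = window_smoothed_classes(track, intervals, classes, cfg)
    out: List[Interval] = []
    for seq_name, labels in track.labels.items():
        wlist = track.windows[seq_name]
        cls = smoothed[seq_name]
        in_block = [False] * len(labels)
        for s, e in _label_runs(labels, lambda lab: lab == "donor"):
            if e - s < cfg.min_run:
                continue
            if any(cls[i] == "introgressed" for i in range(s, e)):
                out.append(Interval(seq_name, wlist[s].start, wlist[e - 1].end, "introgressed"))
                for i in range(s, e):
                    in_block[i] = True
        for s, e in _label_runs(
            [c or "" for c in cls], lambda c: c == "ambiguous"
        ):
            span = [i for i in range(s, e) if not in_block[i]]
            if span:
                out.append(
                    Interval(seq_name, wlist[span[0]].start, wlist[span[-1]].end, "ambiguous")
                )
    out.sort(key=lambda iv: (iv.seq_name, iv.start))
    return out


# ---------------------------------------------------------------------------
# synteny map / projection


@dataclass
class SyntenyMap:
    """Anchor map between two genomes built from uniquely mapped windows."""

    # per query sequence: sorted anchor arrays
    anchors: Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]] = field(default_factory=dict)

    def project_point(
        self, seq_name: str, pos: int, snap: bool = False
    ) -> Optional[Tuple[str, int]]:
        entry = self.anchors.get(seq_name)
        if entry is None:
            raise KeyError(f"no anchors for sequence {seq_name!r}")
        qmids, tmids, tseqs = entry
        if pos < qmids[0] or pos > qmids[-1]:
            return None
        i = int(np.searchsorted(qmids, pos, side="right")) - 1
        if i == qmids.size - 1:
            return tseqs[i], int(tmids[i])
        if tseqs[i] != tseqs[i + 1]:
            if not snap:
                return None  # discontinuity: no interpolation across targets
            j = i if pos - qmids[i] < qmids[i + 1] - pos else i + 1
            return tseqs[j], int(tmids[j])
        q0, q1 = int(qmids[i]), int(qmids[i + 1])
        t0, t1 = int(tmids[i]), int(tmids[i + 1])
        if q1 == q0:
            return tseqs[i], t0
        t = t0 + round((pos - q0) * (t1 - t0) / (q1 - q0))
        return tseqs[i], int(t)

    def project_interval(self, interval: Interval) -> List[Interval]:
        """Project an interval; returns [] when entirely outside anchor
        coverage. Intervals spanning a target-sequence discontinuity are
        split at the query midpoint between the adjacent anchors."""
        entry = self.anchors.get(interval.seq_name)
        if entry is None:
            raise KeyError(f"no anchors for sequence {interval.seq_name!r}")
        qmids, tmids, tseqs = entry
        lo = max(interval.start, int(qmids[0]))
        hi = min(interval.end, int(qmids[-1]) + 1)
        if hi <= lo:
            return []
        # split points: discontinuities between adjacent anchors
        cuts = [lo]
        i0 = int(np.searchsorted(qmids, lo, side="right")) - 1
        i1 = int(np.searchsorted(qmids, hi - 1, side="right")) - 1
        for i in range(max(i0, 0), min(i1, qmids.size - 2) + 1):
            if i + 1 < qmids.size and tseqs[i] != tseqs[i + 1]:
                cut = int((qmids[i] + qmids[i + 1]) // 2)
                if lo < cut < hi:
                    cuts.append(cut)
        cuts.append(hi)
        cuts = sorted(set(cuts))
        out: List[Interval] = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            pa = self.project_point(interval.seq_name, a, snap=True)
            pb = self.project_point(interval.seq_name, b - 1, snap=True)
            if pa is None or pb is None or pa[0] != pb[0]:
                continue
            t_lo, t_hi = min(pa[1], pb[1]), max(pa[1], pb[1]) + 1
            out.append(Interval(pa[0], t_lo, t_hi, interval.label))
        return out


def build_synteny_map(hits: Iterable[WindowHit]) -> SyntenyMap:
    """Anchor map from pruned, one-hit-per-window alignments."""
    by_seq: Dict[str, List[WindowHit]] = {}
    seen: Dict[Tuple[str, int], WindowHit] = {}
    for h in hits:
        key = (h.query_seq, h.qstart)
        if key in seen:
            raise ValueError(f"multiple hits for window {key}; run filters first")
        seen[key] = h
        by_seq.setdefault(h.query_seq, []).append(h)
    smap = SyntenyMap()
    for seq_name, hs in by_seq.items():
        hs.sort(key=lambda h: h.qstart)
        qmids = np.array([(h.qstart + h.qend) // 2 for h in hs], dtype=np.int64)
        tmids = np.array([(h.tstart + h.tend) // 2 for h in hs], dtype=np.int64)
        tseqs = [h.target_seq for h in hs]
        smap.anchors[seq_name] = (qmids, tmids, tseqs)
    return smap


def identity_synteny_map(genome: Genome) -> SyntenyMap:
    """Self-map: every position projects to itself."""
    smap = SyntenyMap()
    for name, length in genome.lengths.items():
        qmids = np.array([0, length - 1], dtype=np.int64)
        smap.anchors[name] = (qmids, qmids.copy(), [name, name])
    return smap


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class ScanResult:
    track: AncestryTrack
    mask: LowDivMask
    seed_blocks: List[Interval]
    smooth_intervals: List[SmoothInterval]
    blocks: List[Interval]

    @property
    def introgressed_blocks(self) -> List[Interval]:
        return [b for b in self.blocks if b.label == "introgressed"]


def run_introgression_scan(
    cultivar: Genome,
    recipient: Genome,
    donor: Genome,
    scan_cfg: ScanConfig = ScanConfig(),
    window_spec: WindowSpec = WindowSpec(10_000, 7_500),
    lowdiv_cfg: LowDivConfig = LowDivConfig(),
    aligner_cfg: AlignerConfig = AlignerConfig(max_secondary=2),
    filter_cfg: FilterConfig = FilterConfig(min_identity=0.99),
    lowdiv_hits: Optional[List[WindowHit]] = None,
    query_hits: Optional[List[WindowHit]] = None,
    synteny: Optional[SyntenyMap] = None,
    apply_lowdiv_mask: bool = True,
) -> ScanResult:
    """Full scan of one cultivar against a recipient/donor trio.

    With ``apply_lowdiv_mask`` off, the low-divergence stage is skipped
    entirely (useful when recipient and donor are known to be separable
    genome-wide, e.g. simulated trios at ~1% divergence where every window
    clears the >98% similarity bar)."""
    if not apply_lowdiv_mask:
        mask = LowDivMask(intervals=[], config=lowdiv_cfg)
        lowdiv_hits = []
    elif lowdiv_hits is None:
        ld_windows = genome_windows(recipient, lowdiv_cfg.window_spec)
        lowdiv_hits = align_windows(recipient, ld_windows, donor, aligner_cfg)
        mask = low_divergence_mask(lowdiv_hits, recipient, lowdiv_cfg)
    else:
        mask = low_divergence_mask(lowdiv_hits, recipient, lowdiv_cfg)

    concat = ConcatRef(recipient=recipient, donor=donor)
    windows = genome_windows(cultivar, window_spec)
    if query_hits is None:
        query_hits = align_windows(cultivar, windows, concat, aligner_cfg)
    if synteny is None:
        # coordinate-preserving queries (simulated cultivars) project 1:1
        synteny = identity_synteny_map(cultivar)
    track = competitive_classify(
        query_hits, concat, windows, mask=mask, synteny=synteny,
        cfg=filter_cfg, genome_id=cultivar.genome_id,
    )
    seeds = seed_blocks(track, scan_cfg)
    smooth = percent_donor_intervals(track, scan_cfg)
    classes = classify_intervals(smooth, scan_cfg)
    blocks = final_blocks(track, smooth, classes, scan_cfg)
    return ScanResult(track=track, mask=mask, seed_blocks=seeds, smooth_intervals=smooth, blocks=blocks)
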