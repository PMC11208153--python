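"""Windowed genome fragmentation, alignment, and hit filtering.

The builtin aligner is a minimizer-anchored, ungapped verifier intended for
desk-scale synthetic genomes: exact k-mer minimizers shared between a query
window and the target are grouped into diagonal-consistent chains, and each
candidate chain is verified by a direct base-wise comparison along its
diagonal. For real assemblies, hits produced externally (minimap2 PAF) can
be imported through :func:`ancestry_scan.genome_io.read_paf` and fed to the
same filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _seqcodes as sc
from .genome_io import ConcatRef, Genome, Interval, WindowHit


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length overlapping window layout."""

    window_len: int = 10_000
    overlap: int = 7_500

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.window_len):
            raise ValueError("require 0 <= overlap < window_len")

    @property
    def step(self) -> int:
        return self.window_len - self.overlap


@dataclass(frozen=True)
class FilterConfig:
    nhits: int = 1
    min_identity: float = 0.98
    min_coverage: float = 0.75
    blk_size: int = 5
    n_window: int = 10
    max_gap: int = 250_000

    def __post_init__(self) -> None:
        if self.nhits < 1:
            raise ValueError("nhits >= 1 required")
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.blk_size > self.n_window:
            raise ValueError("blk_size must be <= n_window")


@dataclass(frozen=True)
class AlignerConfig:
    seed_k: int = 25
    minimizer_window: int = 20
    max_secondary: int = 0
    diag_band: int = 100  # anchors within this diagonal distance chain together

    def __post_init__(self) -> None:
        if self.seed_k < 11:
            raise ValueError("seed_k >= 11 required")


# Parameterizations used by the different pipeline stages.
PRESETS: Dict[str, Tuple[WindowSpec, FilterConfig]] = {
    "synteny": (WindowSpec(10_000, 7_500), FilterConfig(min_identity=0.98)),
    "lowdiv": (WindowSpec(10_000, 5_000), FilterConfig(min_identity=0.99)),
    "introgression": (WindowSpec(10_000, 7_500), FilterConfig(min_identity=0.99)),
    "subgenome": (WindowSpec(10_000, 7_500), FilterConfig(min_identity=0.75)),
}


def make_windows(seq_len: int, spec: WindowSpec, seq_name: str = "") -> List[Interval]:
    """Full-length windows starting at 0, step, 2*step, ...; the trailing
    partial window is dropped."""
    if seq_len < 1:
        raise ValueError("seq_len >= 1 required")
    out = []
    start = 0
    while start + spec.window_len <= seq_len:
        out.append(Interval(seq_name, start, start + spec.window_len))
        start += spec.step
    return out


def genome_windows(genome: Genome, spec: WindowSpec) -> List[Interval]:
    out: List[Interval] = []
    for name, length in genome.lengths.items():
        out.extend(make_windows(length, spec, seq_name=name))
    return out


def _minimizer_positions(kcodes: np.ndarray, w: int) -> np.ndarray:
    """Indices of window minimizers: position of the minimum k-mer code in
    every window of w consecutive k-mers (robust to exact duplicates by
    taking the leftmost). Returns sorted unique positions."""
    n = kcodes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n <= w:
        return np.array([int(np.argmin(kcodes))], dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(kcodes, w)
    mins = view.argmin(axis=1) + np.arange(n - w + 1)
    return np.unique(mins)


class TargetIndex:
    """Sorted minimizer-code index over a (possibly concatenated) target."""

    def __init__(self, target: Genome, cfg: AlignerConfig):
        self.cfg = cfg
        self.seq_names: List[str] = list(target.sequences)
        lengths = [len(target.sequences[n]) for n in self.seq_names]
        self.offsets = np.concatenate(([0], np.cumsum(lengths))).astype(np.int64)
        self.codes = np.concatenate(
            [sc.encode(target.sequences[n]) for n in self.seq_names]
        )
        k, w = cfg.seed_k, cfg.minimizer_window
        kcodes_parts = []
        pos_parts = []
        for i, name in enumerate(self.seq_names):
            seq_codes = self.codes[self.offsets[i] : self.offsets[i + 1]]
            kc = sc.kmer_codes(seq_codes, k)
            mpos = _minimizer_positions(kc, w)
            if mpos.size:
                mcodes = kc[mpos]
                keep = mcodes != sc.POISON
                kcodes_parts.append(mcodes[keep])
                pos_parts.append(mpos[keep] + self.offsets[i])
        if kcodes_parts:
            codes = np.concatenate(kcodes_parts)
            pos = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            self.min_codes = codes[order]
            self.min_pos = pos[order]
        else:
            self.min_codes = np.empty(0, dtype=np.uint64)
            self.min_pos = np.empty(0, dtype=np.int64)

    def seq_index_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def lookup(self, query_kcodes: np.ndarray, query_kpos: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Anchor pairs (query k-mer position, global target position)."""
        lo = np.searchsorted(self.min_codes, query_kcodes, side="left")
        hi = np.searchsorted(self.min_codes, query_kcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(query_kpos, counts)
        # gather ranges [lo_i, hi_i) for each query minimizer
        idx = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
        tpos = self.min_pos[idx]
        return qpos, tpos


def _verify_diagonal(
    index: TargetIndex,
    win_codes: np.ndarray,
    diag: int,
    seq_idx: int,
) -> Optional[Tuple[int, int, int, int]]:
    """Ungapped base comparison of the window against the target along one
    diagonal. Returns (qstart, qend, matches, global_tstart) or None."""
    qlen = win_codes.size
    soff = int(index.offsets[seq_idx])
    send = int(index.offsets[seq_idx + 1])
    # query position q maps to global target position diag + q
    qstart = max(0, soff - diag)
    qend = min(qlen, send - diag)
    if qend - qstart < 1:
        return None
    tslice = index.codes[diag + qstart : diag + qend]
    qslice = win_codes[qstart:qend]
    eq = (tslice == qslice) & (qslice < 4)
    matches = int(eq.sum())
    if matches == 0:
        return None
    return qstart, qend, matches, diag + qstart


def align_windows(
    query: Genome,
    windows: Sequence[Interval],
    target: Union[Genome, ConcatRef],
    cfg: AlignerConfig = AlignerConfig(),
    index: Optional[TargetIndex] = None,
) -> List[WindowHit]:
    """Align each window to the target, returning up to
    ``cfg.max_secondary + 1`` hits per window, best score first."""
    if isinstance(target, ConcatRef):
        target = target.as_genome()
    if index is None:
        index = TargetIndex(target, cfg)
    k, w = cfg.seed_k, cfg.minimizer_window
    hits: List[WindowHit] = []
    window_counters: Dict[str, int] = {}
    q_codes_cache: Dict[str, np.ndarray] = {}
    for win in windows:
        widx = window_counters.get(win.seq_name, 0)
        window_counters[win.seq_name] = widx + 1
        if win.seq_name not in q_codes_cache:
            q_codes_cache[win.seq_name] = sc.encode(query.sequences[win.seq_name])
        win_codes = q_codes_cache[win.seq_name][win.start : win.end]
        qlen = win_codes.size
        cand: List[Tuple[int, WindowHit]] = []
        for strand in "+-":
            codes = win_codes if strand == "+" else sc.revcomp_codes(win_codes)
            kc = sc.kmer_codes(codes, k)
            mpos = _minimizer_positions(kc, w)
            if mpos.size == 0:
                continue
            mcodes = kc[mpos]
            keep = mcodes != sc.POISON
            if not keep.any():
                continue
            qpos, tpos = index.lookup(mcodes[keep], mpos[keep])
            if qpos.size == 0:
                continue
            seq_idx = index.seq_index_of(tpos)
            diags = tpos - qpos
            order = np.lexsort((diags, seq_idx))
            seq_idx, diags, qpos = seq_idx[order], diags[order], qpos[order]
            # split anchor runs on sequence change or diagonal jump
            brk = np.flatnonzero(
                (np.diff(seq_idx) != 0) | (np.abs(np.diff(diags)) > cfg.diag_band)
            )
            starts = np.concatenate(([0], brk + 1))
            ends = np.concatenate((brk + 1, [diags.size]))
            for s, e in zip(starts, ends):
                n_anchors = e - s
                if n_anchors < 2 and qlen >= 2 * k:
                    continue  # demand >=2 consistent anchors on real windows
                diag = int(np.median(diags[s:e]))
                res = _verify_diagonal(index, codes, diag, int(seq_idx[s]))
                if res is None:
                    continue
                qs, qe, matches, gts = res
                block_len = qe - qs
                tname = index.seq_names[int(seq_idx[s])]
                toff = int(index.offsets[int(seq_idx[s])])
                if strand == "+":
                    h_qs, h_qe = qs, qe
                else:  # coordinates back to forward query space
                    h_qs, h_qe = qlen - qe, qlen - qs
                cand.append(
                    (
                        matches,
                        WindowHit(
                            query_seq=win.seq_name,
                            qstart=win.start + h_qs,
                            qend=win.start + h_qe,
                            qlen=qlen,
                            target_seq=tname,
                            tstart=gts - toff,
                            tend=gts - toff + block_len,
                            strand=strand,
                            matches=matches,
                            block_len=block_len,
                            query_window_index=widx,
                        ),
                    )
                )
        # deduplicate overlapping candidates on the same target region
        cand.sort(key=lambda t: -t[0])
        emitted: List[WindowHit] = []
        for _, h in cand:
            dup = any(
                h.target_seq == e.target_seq
                and h.strand == e.strand
                and min(h.tend, e.tend) - max(h.tstart, e.tstart) > 0
                for e in emitted
            )
            if not dup:
                emitted.append(h)
            if len(emitted) > cfg.max_secondary:
                break
        hits.extend(emitted)
    return hits


def filter_hits(
    hits: Iterable[WindowHit],
    cfg: FilterConfig = FilterConfig(),
    return_ties: bool = False,
):
    """Per query window keep the top-``nhits`` hits by score, then drop hits
    below the identity/coverage thresholds. With ``nhits == 1`` an exact
    score tie drops both hits; the tied window keys are returned when
    ``return_ties`` is set so downstream classification can mark them
    ambiguous."""
    hits = list(hits)
    by_query: Dict[Tuple[str, int, int], List[WindowHit]] = {}
    for h in hits:
        by_query.setdefault((h.query_seq, h.qlen, _window_anchor(h)), []).append(h)
    kept_ids = set()
    tied_keys = set()
    for key, group in by_query.items():
        group_sorted = sorted(group, key=lambda h: -h.score)
        if cfg.nhits == 1 and len(group_sorted) > 1 and group_sorted[0].score == group_sorted[1].score:
            tied_keys.add(key)
            continue
        for h in group_sorted[: cfg.nhits]:
            kept_ids.add(id(h))
    out = [
        h
        for h in hits
        if id(h) in kept_ids
        and h.identity >= cfg.min_identity
        and h.coverage >= cfg.min_coverage
    ]
    if return_ties:
        return out, tied_keys
    return out


def _window_anchor(h: WindowHit) -> int:
    """Key identifying the source window of a hit (robust to clipped qstart)."""
    if h.query_window_index >= 0:
        return h.query_window_index
    return h.qstart  # PAF imports: window start == qstart by construction


def prune_collinear(hits: Iterable[WindowHit], cfg: FilterConfig = FilterConfig()) -> List[WindowHit]:
    """Keep hits supported by a collinear neighbourhood.

    Hits are sorted by (query_seq, qstart). For each hit h, the
    neighbourhood is the run of up to ``n_window`` hits nearest in query
    order on the same query sequence, balanced around h and truncated at the
    ends. h is retained iff at least ``blk_size`` neighbourhood hits
    (counting h) share h's target sequence and, ordered by query position,
    have target positions monotone in one direction with every consecutive
    gap at most ``max_gap``.
    """
    hits = sorted(hits, key=lambda h: (h.query_seq, h.qstart))
    by_seq: Dict[str, List[WindowHit]] = {}
    for h in hits:
        by_seq.setdefault(h.query_seq, []).append(h)
    out: List[WindowHit] = []
    for seq_hits in by_seq.values():
        n = len(seq_hits)
        for i, h in enumerate(seq_hits):
            lo = max(0, i - cfg.n_window // 2)
            hi = min(n, lo + cfg.n_window)
            lo = max(0, hi - cfg.n_window)
            neigh = seq_hits[lo:hi]
            if _collinear_support(neigh, h, cfg):
                out.append(h)
    return out


def _collinear_support(neigh: List[WindowHit], h: WindowHit, cfg: FilterConfig) -> bool:
    same = [x for x in neigh if x.target_seq == h.target_seq]
    if len(same) < cfg.blk_size:
        return False
    tmids = [(x.tstart + x.tend) // 2 for x in same]  # already in query order
    gaps = [tmids[j + 1] - tmids[j] for j in range(len(tmids) - 1)]
    inc = all(0 <= g <= cfg.max_gap for g in gaps)
    dec = all(-cfg.max_gap <= g <= 0 for g in gaps)
    return inc or dec
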