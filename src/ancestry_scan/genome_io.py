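"""Coordinate conventions, interval algebra and flat-file readers/writers.

Conventions used everywhere in the package:

* coordinates are 0-based half-open, matching BED;
* sequences are stored uppercase over the alphabet ``{A,C,G,T,N}``; any
  other character is squashed to ``N`` at read time (the squash count is
  recorded on the :class:`Genome`);
* PAF identity is residue matches / alignment block length, and query
  coverage is aligned query span / query length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Genome:
    """A named collection of nucleotide sequences.

    ``sequences`` preserves insertion order; ``lengths`` always mirrors it.
    """

    genome_id: str
    sequences: Dict[str, str] = field(default_factory=dict)
    squashed_bases: int = 0

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence {name!r} in genome {self.genome_id!r}")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with an optional label."""

    seq_name: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.seq_name}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start},{self.end}) on {self.seq_name}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def bound_check(self, genome: Genome) -> None:
        length = genome.lengths.get(self.seq_name)
        if length is None:
            raise ValueError(f"sequence {self.seq_name!r} not in genome {genome.genome_id!r}")
        if self.end > length:
            raise ValueError(
                f"interval [{self.start},{self.end}) exceeds {self.seq_name} length {length}"
            )


@dataclass
class ConcatRef:
    """Recipient and donor genomes treated as a single competitive target.

    Sequence names are prefixed with the genome id (``<genome_id>#<name>``)
    so the origin of any hit is recoverable via :meth:`origin_of`.
    """

    recipient: Genome
    donor: Genome

    SEP = "#"

    def __post_init__(self) -> None:
        if self.recipient.genome_id == self.donor.genome_id:
            raise ValueError("recipient and donor must have distinct genome ids")

    def target_name(self, origin: str, seq_name: str) -> str:
        gid = {"recipient": self.recipient.genome_id, "donor": self.donor.genome_id}[origin]
        return f"{gid}{self.SEP}{seq_name}"

    def as_genome(self) -> Genome:
        seqs: Dict[str, str] = {}
        for origin, g in (("recipient", self.recipient), ("donor", self.donor)):
            for name, seq in g.sequences.items():
                tname = f"{g.genome_id}{self.SEP}{name}"
                if tname in seqs:
                    raise ValueError(f"target name collision: {tname}")
                seqs[tname] = seq
        return Genome(genome_id=f"{self.recipient.genome_id}+{self.donor.genome_id}", sequences=seqs)

    def origin_of(self, target_seq: str) -> str:
        gid, _, _ = target_seq.partition(self.SEP)
        if gid == self.recipient.genome_id:
            return "recipient"
        if gid == self.donor.genome_id:
            return "donor"
        raise KeyError(f"target sequence {target_seq!r} not from this ConcatRef")

    def source_name(self, target_seq: str) -> str:
        return target_seq.partition(self.SEP)[2]


@dataclass
class WindowHit:
    """One window-to-target alignment record (PAF semantics)."""

    query_seq: str
    qstart: int
    qend: int
    qlen: int
    target_seq: str
    tstart: int
    tend: int
    strand: str
    matches: int
    block_len: int
    query_window_index: int = -1

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0

    @property
    def coverage(self) -> float:
        return (self.qend - self.qstart) / self.qlen if self.qlen else 0.0

    @property
    def score(self) -> int:
        return self.matches

    @property
    def query_key(self) -> Tuple[str, int]:
        return (self.query_seq, self.qstart)


def _clean_sequence(raw: str) -> Tuple[str, int]:
    seq = raw.upper()
    squashed = 0
    if not set(seq) <= _VALID:
        chars = []
        for c in seq:
            if c in _VALID:
                chars.append(c)
            else:
                chars.append("N")
                squashed += 1
        seq = "".join(chars)
    return seq, squashed


def read_fasta(path: Union[str, Path], genome_id: Optional[str] = None) -> Genome:
    """Read a (multi-record, wrapped or unwrapped) FASTA file into a Genome.

    Characters outside {A,C,G,T,N} are replaced by N; the replacement count
    is stored on ``Genome.squashed_bases`` and logged.
    """
    path = Path(path)
    gid = genome_id or path.stem
    sequences: Dict[str, str] = {}
    name: Optional[str] = None
    chunks: List[str] = []
    total_squashed = 0

    def _flush() -> None:
        nonlocal total_squashed
        if name is None:
            return
        seq, squashed = _clean_sequence("".join(chunks))
        if not seq:
            raise FormatError(f"empty record {name!r} in {path}")
        total_squashed += squashed
        sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                if not name:
                    raise FormatError(f"unnamed FASTA record in {path}")
                if name in sequences:
                    raise FormatError(f"duplicate record name {name!r} in {path}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"sequence data before first header in {path}")
                chunks.append(line)
    _flush()
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    if total_squashed:
        logger.info("squashed %d non-ACGTN characters to N in %s", total_squashed, path)
    return Genome(genome_id=gid, sequences=sequences, squashed_bases=total_squashed)


def write_fasta(genome: Genome, path: Union[str, Path], line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_bed(
    intervals: Iterable[Interval],
    path: Union[str, Path],
    genome: Optional[Genome] = None,
) -> None:
    """Write intervals as BED3/BED4 (0-based half-open) in input order."""
    intervals = list(intervals)
    if genome is not None:
        for iv in intervals:
            iv.bound_check(genome)
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is not None:
                fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\n")


def read_bed(path: Union[str, Path]) -> List[Interval]:
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            label = cols[3] if len(cols) > 3 else None
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), label))
    return out


def read_paf(path: Union[str, Path]) -> List[WindowHit]:
    """Parse a 12+-column PAF file into WindowHit records (order preserved)."""
    hits: List[WindowHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >=12 columns, got {len(cols)}")
            hits.append(
                WindowHit(
                    query_seq=cols[0],
                    qlen=int(cols[1]),
                    qstart=int(cols[2]),
                    qend=int(cols[3]),
                    strand=cols[4],
                    target_seq=cols[5],
                    tstart=int(cols[7]),
                    tend=int(cols[8]),
                    matches=int(cols[9]),
                    block_len=int(cols[10]),
                )
            )
    return hits


def write_paf(hits: Iterable[WindowHit], path: Union[str, Path], tlens: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        for h in hits:
            tlen = (tlens or {}).get(h.target_seq, h.tend)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_seq, h.qlen, h.qstart, h.qend, h.strand,
                        h.target_seq, tlen, h.tstart, h.tend,
                        h.matches, h.block_len, 60,
                    )
                )
                + "\n"
            )


def merge_intervals(intervals: Iterable[Interval], max_gap: int = 0) -> List[Interval]:
    """Coalesce, per sequence, intervals that overlap or lie within
    ``max_gap`` bases of each other. Output is sorted by (seq_name, start).
    Labels are dropped on merge."""
    by_seq: Dict[str, List[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_name, []).append(iv)
    out: List[Interval] = []
    for seq_name in sorted(by_seq):
        ivs = sorted(by_seq[seq_name], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(seq_name, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(seq_name, cur_start, cur_end))
    return out


def covered_bases(intervals: Iterable[Interval]) -> int:
    """Total bases covered by the union of the intervals."""
    intervals = list(intervals)
    if not intervals:
        return 0
    return sum(iv.width for iv in merge_intervals(intervals))


def overlap_bases(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Bases covered by both interval sets (intersection of unions)."""
    a = list(a)
    b = list(b)
    if not a or not b:
        return 0
    am = merge_intervals(a)
    bm = merge_intervals(b)
    by_seq_b: Dict[str, List[Interval]] = {}
    for iv in bm:
        by_seq_b.setdefault(iv.seq_name, []).append(iv)
    total = 0
    for iv in am:
        for jv in by_seq_b.get(iv.seq_name, ()):  # both lists are sorted & disjoint
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if hi > lo:
                total += hi - lo
    return total


def jaccard(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    """Intersection bases / union bases of two interval sets."""
    a = list(a)
    b = list(b)
    inter = overlap_bases(a, b)
    union = covered_bases(a) + covered_bases(b) - inter
    return inter / union if union else 0.0
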