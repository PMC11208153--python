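"""Synthetic recipient/donor/cultivar trios with planted truth.

All generators are pure functions of (config, seed): the recipient is an
i.i.d. background with optional centromeric arrays and telomeric ends, the
donor is a per-base substitution mutant of the recipient (with optional
zero-divergence segments), and cultivars are the recipient with planted
donor blocks replaced coordinate-for-coordinate.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _seqcodes as sc
from .genome_io import Genome, Interval, write_bed, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CentromerePlan:
    seq_name: str
    monomer: str
    array_len: int
    position: int  # array start offset


@dataclass
class SimConfig:
    n_chroms: int = 3
    chrom_len: int = 1_000_000
    divergence: float = 0.01
    private_rate: float = 0.0
    lowdiv_segments: List[Tuple[str, int, int]] = field(default_factory=list)
    introgressions: List[Tuple[str, int, int]] = field(default_factory=list)
    centromeres: List[CentromerePlan] = field(default_factory=list)
    telomere_copies: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.25):
            raise ValueError("divergence must lie in [0, 0.25]")
        self._check_plan(self.lowdiv_segments, "lowdiv_segments")
        self._check_plan(self.introgressions, "introgressions")
        for cen in self.centromeres:
            if cen.position + cen.array_len > self.chrom_len:
                raise ValueError(f"centromeric array exceeds {cen.seq_name} bounds")

    def _check_plan(self, plan: Sequence[Tuple[str, int, int]], what: str) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in plan:
            if not (0 <= start < end <= self.chrom_len):
                raise ValueError(f"{what}: ({chrom},{start},{end}) outside chromosome bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"{what}: overlapping planned intervals on {chrom}")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["centromeres"] = [dataclasses.asdict(c) for c in self.centromeres]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["centromeres"] = [CentromerePlan(**c) for c in d.get("centromeres", [])]
        d["lowdiv_segments"] = [tuple(x) for x in d.get("lowdiv_segments", [])]
        d["introgressions"] = [tuple(x) for x in d.get("introgressions", [])]
        return cls(**d)


@dataclass
class TruthSet:
    """Planted-feature intervals on cultivar coordinates."""

    introgressions: List[Interval] = field(default_factory=list)
    lowdiv: List[Interval] = field(default_factory=list)
    centromeres: List[Interval] = field(default_factory=list)
    telomeres: Dict[str, Tuple[bool, bool]] = field(default_factory=dict)


def _rng_for(cfg: SimConfig, stream: str) -> np.random.Generator:
    # crc32, not hash(): str hashing is salted per process
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def simulate_recipient(cfg: SimConfig) -> Genome:
    """i.i.d. uniform background with planted centromeric arrays and
    telomeric termini; deterministic given cfg.seed."""
    rng = _rng_for(cfg, "recipient")
    cens = {c.seq_name: c for c in cfg.centromeres}
    sequences: Dict[str, str] = {}
    for name in cfg.chrom_names:
        arr = _BASES[rng.integers(0, 4, size=cfg.chrom_len)]
        if name in cens:
            cen = cens[name]
            monomer = np.frombuffer(cen.monomer.encode(), dtype=np.uint8)
            reps = int(np.ceil(cen.array_len / len(cen.monomer)))
            tile = np.tile(monomer, reps)[: cen.array_len]
            arr[cen.position : cen.position + cen.array_len] = tile
        if cfg.telomere_copies > 0:
            head = np.frombuffer(b"CCCTAAA" * cfg.telomere_copies, dtype=np.uint8)
            tail = np.frombuffer(b"TTTAGGG" * cfg.telomere_copies, dtype=np.uint8)
            arr[: head.size] = head
            arr[arr.size - tail.size :] = tail
        sequences[name] = arr.tobytes().decode("ascii")
    return Genome(genome_id="recipient", sequences=sequences)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a uniformly chosen
    different base."""
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        codes = sc._ENCODE[out[hit]].astype(np.int64)
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(codes + shift) % 4]
    return out


def derive_donor(recipient: Genome, cfg: SimConfig) -> Genome:
    """Per-base substitution mutant of the recipient; lowdiv segments are
    copied verbatim."""
    rng = _rng_for(cfg, "donor")
    lowdiv: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in cfg.lowdiv_segments:
        lowdiv.setdefault(chrom, []).append((start, end))
    sequences: Dict[str, str] = {}
    for name, seq in recipient.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mutated = _mutate(arr, cfg.divergence, rng)
        for start, end in lowdiv.get(name, ()):
            mutated[start:end] = arr[start:end]
        sequences[name] = mutated.tobytes().decode("ascii")
    return Genome(genome_id="donor", sequences=sequences)


def build_cultivar(
    recipient: Genome,
    donor: Genome,
    cfg: SimConfig,
    genome_id: str = "cultivar",
) -> Tuple[Genome, TruthSet]:
    """Recipient with planned introgression intervals replaced by the
    donor's bases over the same coordinates (plus optional private
    substitutions)."""
    if recipient.lengths != donor.lengths:
        raise ValueError("recipient and donor must share chromosome structure")
    rng = _rng_for(cfg, "cultivar")
    plan: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in cfg.introgressions:
        plan.setdefault(chrom, []).append((start, end))
    sequences: Dict[str, str] = {}
    for name, seq in recipient.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        darr = np.frombuffer(donor.sequences[name].encode(), dtype=np.uint8)
        for start, end in plan.get(name, ()):
            arr[start:end] = darr[start:end]
        if cfg.private_rate > 0:
            arr = _mutate(arr, cfg.private_rate, rng)
        sequences[name] = arr.tobytes().decode("ascii")
    truth = TruthSet(
        introgressions=[Interval(c, s, e, "introgression") for c, s, e in cfg.introgressions],
        lowdiv=[Interval(c, s, e, "lowdiv") for c, s, e in cfg.lowdiv_segments],
        centromeres=[
            Interval(c.seq_name, c.position, c.position + c.array_len, "centromere")
            for c in cfg.centromeres
        ],
        telomeres={
            name: (cfg.telomere_copies > 0, cfg.telomere_copies > 0)
            for name in cfg.chrom_names
        },
    )
    return Genome(genome_id=genome_id, sequences=sequences), truth


def simulate_trio(cfg: SimConfig) -> Tuple[Genome, Genome, Genome, TruthSet]:
    recipient = simulate_recipient(cfg)
    donor = derive_donor(recipient, cfg)
    cultivar, truth = build_cultivar(recipient, donor, cfg)
    return recipient, donor, cultivar, truth


def write_fixture(
    genomes: Sequence[Genome],
    truth: TruthSet,
    cfg: SimConfig,
    out_dir,
) -> List[Path]:
    """Write FASTA + truth BED/TSV + a JSON manifest capturing the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for g in genomes:
        p = out_dir / f"{g.genome_id}.fa"
        write_fasta(g, p)
        written.append(p)
    for name, ivs in (
        ("truth.introgressions.bed", truth.introgressions),
        ("truth.lowdiv.bed", truth.lowdiv),
        ("truth.centromeres.bed", truth.centromeres),
    ):
        p = out_dir / name
        write_bed(ivs, p)
        written.append(p)
    p = out_dir / "truth.telomeres.tsv"
    with open(p, "w") as fh:
        fh.write("seq_name\tstart_telomere\tend_telomere\n")
        for name, (s, e) in truth.telomeres.items():
            fh.write(f"{name}\t{int(s)}\t{int(e)}\n")
    written.append(p)
    p = out_dir / "manifest.json"
    with open(p, "w") as fh:
        json.dump({"sim_config": cfg.to_dict()}, fh, indent=2)
    written.append(p)
    return written
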