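import numpy as np
import pytest

from ancestry_scan.genome_io import Genome, Interval, WindowHit

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(n: int, rng: np.random.Generator) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_hit(
    query_seq="q1",
    qstart=0,
    qlen=10_000,
    target_seq="t1",
    tstart=0,
    matches=10_000,
    block_len=10_000,
    strand="+",
    qend=None,
    tend=None,
    window_index=-1,
) -> WindowHit:
    return WindowHit(
        query_seq=query_seq,
        qstart=qstart,
        qend=qend if qend is not None else qstart + qlen,
        qlen=qlen,
        target_seq=target_seq,
        tstart=tstart,
        tend=tend if tend is not None else tstart + block_len,
        strand=strand,
        matches=matches,
        block_len=block_len,
        query_window_index=window_index,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome(rng):
    return Genome(
        genome_id="toy",
        sequences={"chrA": random_seq(10_000, rng), "chrB": random_seq(8_000, rng)},
    )


def random_intervals(n, seq_names, seq_lens, rng, max_width=500):
    out = []
    for _ in range(n):
        name = seq_names[rng.integers(0, len(seq_names))]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, max(1, seq_lens[name] - width)))
        out.append(Interval(name, start, start + width))
    return out


def coverage_mask(intervals, seq_name, seq_len):
    """Brute-force boolean coverage array (the per-base oracle)."""
    mask = np.zeros(seq_len, dtype=bool)
    for iv in intervals:
        if iv.seq_name == seq_name:
            mask[iv.start : iv.end] = True
    return mask
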