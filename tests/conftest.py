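"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from hacseq.refio import Category, Transcript, TranscriptSet
from hacseq.coverage import ReadRecord


def brute_force_count(reads, lengths):
    """Independent nested-loop oracle for start/depth counting.

    Iterates every read and, for depth, every covered position — no
    shared code with the package's vectorized counting path.
    """
    starts = {tid: [0] * L for tid, L in lengths.items()}
    depth = {tid: [0] * L for tid, L in lengths.items()}
    for r in reads:
        starts[r.transcript_id][r.start - 1] += 1
        for pos in range(r.start, r.end + 1):
            depth[r.transcript_id][pos - 1] += 1
    return starts, depth


def random_transcripts(rng: np.random.Generator, n: int, min_len=30, max_len=120):
    ts = TranscriptSet()
    for k in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGU"), size=L))
        ts.add(Transcript(f"t{k}", seq, Category.OTHER))
    return ts


def random_reads(rng: np.random.Generator, ts: TranscriptSet, n: int):
    ids = ts.ids()
    reads = []
    for _ in range(n):
        tid = ids[int(rng.integers(len(ids)))]
        L = len(ts[tid])
        start = int(rng.integers(1, L + 1))
        end = int(rng.integers(start, L + 1))
        reads.append(ReadRecord(tid, start, end))
    return reads


@pytest.fixture
def tiny_transcripts() -> TranscriptSet:
    ts = TranscriptSet()
    ts.add(Transcript("tx1", "ACGUACGUAC", Category.OTHER))
    ts.add(Transcript("tx2", "GGGCCCAAAUUU", Category.OTHER))
    return ts


def write_panel_inputs(outdir: Path, transcripts, truth) -> dict[str, Path]:
    """Serialize a panel (FASTA, truth TSV, labels TSV) for CLI runs."""
    from hacseq.refio import write_fasta

    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "refs.fasta"
    write_fasta(transcripts, fasta)
    truth_tsv = outdir / "truth.tsv"
    truth.to_tsv(truth_tsv)
    labels = outdir / "labels.tsv"
    with open(labels, "w") as fh:
        fh.write("transcript_id\tposition\tlabel\n")
        for t in transcripts:
            for pos, lab in sorted(t.labels.items()):
                fh.write(f"{t.id}\t{pos}\t{lab}\n")
    return {"fasta": fasta, "truth": truth_tsv, "labels": labels}
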