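"""Per-position read-start and depth counting.

The cleavage-ratio statistic is built from two length-L integer vectors
per transcript and sample: ``starts[i]``, the number of retained reads
whose 5'-most aligned reference base is position i, and ``depth[i]``,
the number of retained reads covering position i.  Reads arrive either
as alignments (SAM/BAM, consumed with pysam using standard pileup
semantics) or as a plain 3-column TSV of (transcript_id, start, end)
records — the aligner-free path used by the simulator.

Coordinates are 1-based inclusive throughout this package; conversion to
0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from hacseq.refio import TranscriptSet

#: The three experiment arms: untreated control, hydrazine-aniline
#: cleaved, and demethylated-then-cleaved.
GROUPS = ("Ctrl", "HAC", "DM-HAC")

#: Sample key: (group, replicate index), replicates numbered from 1.
SampleKey = tuple[str, int]


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read as a closed interval on a transcript."""

    transcript_id: str
    start: int  # 1-based, 5'-most aligned reference base
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"read on {self.transcript_id!r}: invalid interval "
                f"[{self.start}, {self.end}]"
            )


@dataclass
class CoverageProfile:
    """starts/depth vectors for one transcript in one sample."""

    transcript_id: str
    starts: np.ndarray
    depth: np.ndarray
    group: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.starts.shape != self.depth.shape or self.starts.ndim != 1:
            raise ValueError("starts and depth must be 1-D vectors of equal length")

    @property
    def length(self) -> int:
        return self.starts.size

    def validate(self) -> None:
        """Assert the structural invariants (starts[i] <= depth[i], >= 0)."""
        if (self.starts < 0).any() or (self.depth < 0).any():
            raise ValueError(f"{self.transcript_id}: negative counts")
        if (self.starts > self.depth).any():
            raise ValueError(
                f"{self.transcript_id}: starts exceeds depth "
                "(a read starting at i must cover i)"
            )


def _empty_profiles(
    transcripts: TranscriptSet, group: str | None, replicate: int | None
) -> dict[str, CoverageProfile]:
    return {
        t.id: CoverageProfile(
            t.id,
            np.zeros(len(t), dtype=np.int64),
            np.zeros(len(t), dtype=np.int64),
            group=group,
            replicate=replicate,
        )
        for t in transcripts
    }


def count_reads(
    reads: Iterable[ReadRecord],
    transcripts: TranscriptSet,
    *,
    group: str | None = None,
    replicate: int | None = None,
) -> dict[str, CoverageProfile]:
    """Count ReadRecords into per-transcript profiles.

    Depth here is span coverage: a record [start, end] covers every
    position in between.  Unknown transcript ids (after alias
    resolution) and out-of-bounds intervals are errors.
    """
    profiles = _empty_profiles(transcripts, group, replicate)
    # accumulate depth as a difference array per transcript, cumsum at the end
    diffs = {tid: np.zeros(p.length + 1, dtype=np.int64) for tid, p in profiles.items()}
    for r in reads:
        tid = transcripts.resolve(r.transcript_id)  # KeyError names unknowns
        prof = profiles[tid]
        if r.end > prof.length:
            raise ValueError(
                f"read [{r.start}, {r.end}] exceeds length {prof.length} "
                f"of transcript {tid!r}"
            )
        prof.starts[r.start - 1] += 1
        d = diffs[tid]
        d[r.start - 1] += 1
        d[r.end] -= 1
    for tid, prof in profiles.items():
        prof.depth = np.cumsum(diffs[tid][:-1])
    return profiles


def count_tsv(
    path: str | Path,
    transcripts: TranscriptSet,
    *,
    group: str | None = None,
    replicate: int | None = None,
) -> dict[str, CoverageProfile]:
    """Count a ReadRecord TSV (columns transcript_id, start, end)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"transcript_id": str, "start": np.int64, "end": np.int64},
    )
    required = {"transcript_id", "start", "end"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    reads = (
        ReadRecord(tid, int(s), int(e))
        for tid, s, e in zip(frame["transcript_id"], frame["start"], frame["end"])
    )
    return count_reads(reads, transcripts, group=group, replicate=replicate)


def count_sam(
    path: str | Path,
    transcripts: TranscriptSet,
    *,
    min_mapq: int = 0,
    primary_only: bool = True,
    include_reverse: bool = False,
    group: str | None = None,
    replicate: int | None = None,
) -> dict[str, CoverageProfile]:
    """Count a SAM/BAM file into per-transcript profiles.

    Unmapped, secondary and supplementary alignments are skipped (the
    latter two only counted when ``primary_only`` is off); reverse-strand
    alignments are dropped unless ``include_reverse``, in which case the
    read's 5' end (the highest reference coordinate) is counted as the
    start.  Soft clips never contribute; the start is the first
    reference-consumed base and depth accrues over aligned blocks only,
    so deletions and splices leave gaps in depth.
    """
    profiles = _empty_profiles(transcripts, group, replicate)
    diffs = {tid: np.zeros(p.length + 1, dtype=np.int64) for tid, p in profiles.items()}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if primary_only and (aln.is_secondary or aln.is_supplementary):
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.is_reverse and not include_reverse:
                continue
            name = aln.reference_name
            try:
                tid = transcripts.resolve(name)
            except KeyError as err:
                raise ValueError(
                    f"{path}: alignment to unknown reference {name!r}"
                ) from err
            prof = profiles[tid]
            start = aln.reference_start + 1          # 1-based first consumed base
            end = aln.reference_end                  # 1-based inclusive
            if not 1 <= start <= end <= prof.length:
                raise ValueError(
                    f"{path}: alignment [{start}, {end}] outside 1..{prof.length} "
                    f"on {tid!r}"
                )
            start_pos = end if aln.is_reverse else start
            prof.starts[start_pos - 1] += 1
            d = diffs[tid]
            for block_start, block_end in aln.get_blocks():  # 0-based half-open
                d[block_start] += 1
                d[block_end] -= 1
    for tid, prof in profiles.items():
        prof.depth = np.cumsum(diffs[tid][:-1])
    return profiles


def count_from_alignments(
    source: str | Path,
    transcripts: TranscriptSet,
    *,
    min_mapq: int = 0,
    primary_only: bool = True,
    include_reverse: bool = False,
    group: str | None = None,
    replicate: int | None = None,
) -> dict[str, CoverageProfile]:
    """Dispatch counting by file type: .sam/.bam/.cram via pysam, else TSV."""
    suffix = Path(source).suffix.lower()
    if suffix in {".sam", ".bam", ".cram"}:
        return count_sam(
            source,
            transcripts,
            min_mapq=min_mapq,
            primary_only=primary_only,
            include_reverse=include_reverse,
            group=group,
            replicate=replicate,
        )
    return count_tsv(source, transcripts, group=group, replicate=replicate)


def add_profiles(
    a: Mapping[str, CoverageProfile], b: Mapping[str, CoverageProfile]
) -> dict[str, CoverageProfile]:
    """Element-wise sum of two profile collections (same transcripts)."""
    if set(a) != set(b):
        raise ValueError("profile collections cover different transcripts")
    out: dict[str, CoverageProfile] = {}
    for tid, pa in a.items():
        pb = b[tid]
        if pa.length != pb.length:
            raise ValueError(f"{tid}: length mismatch {pa.length} vs {pb.length}")
        out[tid] = CoverageProfile(
            tid, pa.starts + pb.starts, pa.depth + pb.depth,
            group=pa.group, replicate=pa.replicate,
        )
    return out


def write_coverage_tsv(
    profiles: Mapping[str, CoverageProfile], path: str | Path
) -> None:
    """Serialize profiles as (transcript_id, position, starts, depth) rows."""
    chunks = []
    for tid in profiles:
        p = profiles[tid]
        chunks.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "position": np.arange(1, p.length + 1),
                    "starts": p.starts,
                    "depth": p.depth,
                }
            )
        )
    frame = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["transcript_id", "position", "starts", "depth"])
    )
    frame.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(
    path: str | Path,
    transcripts: TranscriptSet,
    *,
    group: str | None = None,
    replicate: int | None = None,
) -> dict[str, CoverageProfile]:
    """Load profiles written by :func:`write_coverage_tsv`."""
    frame = pd.read_csv(path, sep="\t")
    profiles = _empty_profiles(transcripts, group, replicate)
    for tid, sub in frame.groupby("transcript_id", sort=False):
        rep_id = transcripts.resolve(str(tid))
        prof = profiles[rep_id]
        pos = sub["position"].to_numpy()
        if pos.min() < 1 or pos.max() > prof.length:
            raise ValueError(f"{path}: positions outside 1..{prof.length} for {tid!r}")
        prof.starts[pos - 1] = sub["starts"].to_numpy()
        prof.depth[pos - 1] = sub["depth"].to_numpy()
    return profiles
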