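"""Generative simulator of three-arm hydrazine-aniline cleavage libraries.

The simulator plays the library chemistry forward, molecule by molecule,
so the pipeline can be tested against planted ground truth:

1. every planted 3-methylcytidine site marks a molecule with probability
   equal to its stoichiometry ``s``;
2. in the demethylated arm (DM-HAC) each mark is erased with the site's
   demethylation efficiency ``d`` (AlkB pre-treatment);
3. the molecule fragments randomly — every internucleotide bond breaks
   independently with probability ``break_prob`` — and all fragmentation
   ends are repaired, hence ligatable;
4. in the two cleaved arms (HAC, DM-HAC) every still-marked site on a
   fragment is cleaved with efficiency ``c``: cleavage excises the
   marked base and destroys everything 5' of it (the 5' piece keeps a
   damaged 3' end and cannot be adapter-ligated), so the surviving piece
   begins one base 3' of the 3'-most realized cleavage;
5. a pre-library demethylation erases surviving marks in every arm;
   with probability ``rt_stop_prob`` a surviving mark instead arrests
   reverse transcription, truncating the read to begin one base 3' of
   the mark;
6. fragments outside the retained size window are lost; each survivor
   becomes one read spanning [start, end] on the transcript.

Randomness is split into two deterministic streams per (replicate,
transcript): a pre-cleavage stream shared by all three arms (marking and
fragmentation draw the same numbers in every arm) and an arm-specific
stream for demethylation/cleavage/RT-stop draws.  With stoichiometry
zero the cleaved arms therefore reproduce the control arm read-for-read,
and identical (inputs, seed) give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from hacseq.coverage import GROUPS, ReadRecord, SampleKey
from hacseq.refio import TranscriptSet


@dataclass(frozen=True)
class TruthSite:
    """One planted modification site.

    stoichiometry: fraction of molecules carrying the mark.
    demethylation: probability AlkB erases the mark (DM-HAC arm).
    cleavage: optional per-site override of the global cleavage
        efficiency (None = use the experiment-wide value).
    """

    transcript_id: str
    position: int
    stoichiometry: float
    demethylation: float = 1.0
    cleavage: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"truth site position {self.position} must be >= 1")
        for name in ("stoichiometry", "demethylation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.cleavage is not None and not 0.0 <= self.cleavage <= 1.0:
            raise ValueError(f"cleavage {self.cleavage} outside [0, 1]")


class ModificationTruth:
    """Planted-site table: at most one record per (transcript, position)."""

    def __init__(self, sites: Iterable[TruthSite] = ()) -> None:
        self.sites: list[TruthSite] = []
        seen: set[tuple[str, int]] = set()
        for s in sites:
            key = (s.transcript_id, s.position)
            if key in seen:
                raise ValueError(f"duplicate truth site {key}")
            seen.add(key)
            self.sites.append(s)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def by_transcript(self, transcript_id: str) -> list[TruthSite]:
        return sorted(
            (s for s in self.sites if s.transcript_id == transcript_id),
            key=lambda s: s.position,
        )

    def positions(self) -> set[tuple[str, int]]:
        return {(s.transcript_id, s.position) for s in self.sites}

    def validate(self, transcripts: TranscriptSet, *, require_c: bool = True) -> None:
        """Check sites against references; by default the planted base must
        be C (relaxable for negative-control experiments)."""
        for s in self.sites:
            if s.transcript_id not in transcripts:
                raise ValueError(f"truth site on unknown transcript {s.transcript_id!r}")
            t = transcripts[s.transcript_id]
            if not 1 <= s.position <= len(t):
                raise ValueError(
                    f"truth site {s.transcript_id}:{s.position} outside 1..{len(t)}"
                )
            if require_c and t.base(s.position) != "C":
                raise ValueError(
                    f"truth site {s.transcript_id}:{s.position} is on base "
                    f"{t.base(s.position)!r}, not C"
                )

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [
                {
                    "transcript_id": s.transcript_id,
                    "position": s.position,
                    "stoichiometry": s.stoichiometry,
                    "demethylation": s.demethylation,
                    "cleavage": "" if s.cleavage is None else s.cleavage,
                }
                for s in self.sites
            ],
            columns=["transcript_id", "position", "stoichiometry", "demethylation", "cleavage"],
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModificationTruth":
        frame = pd.read_csv(path, sep="\t", comment="#")
        sites = []
        for row in frame.itertuples(index=False):
            c = getattr(row, "cleavage", None)
            c = None if c is None or (isinstance(c, float) and np.isnan(c)) or c == "" else float(c)
            sites.append(
                TruthSite(
                    str(row.transcript_id),
                    int(row.position),
                    float(row.stoichiometry),
                    float(getattr(row, "demethylation", 1.0)),
                    c,
                )
            )
        return cls(sites)


@dataclass
class SimulationConfig:
    """Library-generation parameters.

    molecules is the number of full-length molecules per transcript per
    replicate.  break_prob is the per-bond fragmentation probability
    (default 1/200, i.e. mean fragment around 200 nt for long RNAs —
    tRNA-length molecules mostly stay intact, as in a lightly fragmented
    small-RNA library).  The retained size window [frag_min, frag_max]
    models library size selection.  rt_stop_prob is the residual
    reverse-transcription hard-stop probability per surviving mark; the
    protocol demethylates before library prep, so it defaults to 0.
    """

    seed: int
    replicates: int = 2
    molecules: int = 1000
    break_prob: float = 0.005
    cleavage: float = 1.0
    rt_stop_prob: float = 0.0
    frag_min: int = 15
    frag_max: int = 300
    max_read_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("break_prob", "cleavage", "rt_stop_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.molecules < 1 or self.replicates < 1:
            raise ValueError("molecules and replicates must be >= 1")
        if self.frag_min > self.frag_max:
            raise ValueError("frag_min must not exceed frag_max")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_mapping(cls, data: Mapping, *, seed: int | None = None) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown simulation config keys {sorted(unknown)}")
        merged = dict(data)
        if seed is not None:
            merged["seed"] = seed
        if "seed" not in merged:
            raise ValueError("seed must be given in the config or on the command line")
        return cls(**merged)


@dataclass
class SimulatedExperiment:
    """Reads per (group, replicate) plus the truth that generated them."""

    transcripts: TranscriptSet
    truth: ModificationTruth
    config: SimulationConfig
    reads: dict[SampleKey, list[ReadRecord]]

    def sample_keys(self) -> list[SampleKey]:
        return list(self.reads)

    def write(self, outdir: str | Path, *, sam: bool = True) -> Path:
        """Write per-sample reads (TSV and optionally SAM), the truth
        table, and a sample sheet pointing at the TSVs.  Returns the
        sample-sheet path.  File names inside the sheet are relative to
        the output directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (group, rep), reads in self.reads.items():
            stem = f"{group}_rep{rep}"
            tsv = outdir / f"{stem}.reads.tsv"
            write_reads_tsv(reads, tsv)
            if sam:
                write_sam(reads, self.transcripts, outdir / f"{stem}.sam")
            rows.append({"file": tsv.name, "group": group, "replicate": rep})
        self.truth.to_tsv(outdir / "truth.tsv")
        sheet = outdir / "sample_sheet.tsv"
        pd.DataFrame(rows, columns=["file", "group", "replicate"]).to_csv(
            sheet, sep="\t", index=False
        )
        return sheet


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _simulate_sample(
    group_idx: int,
    replicate: int,
    transcripts: TranscriptSet,
    truth: ModificationTruth,
    cfg: SimulationConfig,
) -> list[ReadRecord]:
    group = GROUPS[group_idx]
    cleaving_arm = group in ("HAC", "DM-HAC")
    demethylating_arm = group == "DM-HAC"
    reads: list[ReadRecord] = []
    for t_index, t in enumerate(transcripts):
        sites = truth.by_transcript(t.id)
        n_sites = len(sites)
        positions = [s.position for s in sites]
        stoich = np.array([s.stoichiometry for s in sites])
        demeth = [s.demethylation for s in sites]
        cleave_p = [cfg.cleavage if s.cleavage is None else s.cleavage for s in sites]
        L = len(t)
        # pre-cleavage stream is identical in all three arms; arm stream is not
        mol_rng = _stream(cfg.seed, 0, replicate, t_index)
        arm_rng = _stream(cfg.seed, 1, group_idx, replicate, t_index)
        for _ in range(cfg.molecules):
            # constant draw count per molecule keeps arms in lock-step
            marked = mol_rng.random(n_sites) < stoich
            breaks = np.flatnonzero(mol_rng.random(L - 1) < cfg.break_prob)
            marks = [k for k in range(n_sites) if marked[k]]
            if demethylating_arm and marks:
                marks = [k for k in marks if arm_rng.random() >= demeth[k]]
            # fragments partition [1, L]
            bounds = [0, *(int(b) + 1 for b in breaks), L]
            for a0, b in zip(bounds[:-1], bounds[1:]):
                a = a0 + 1
                start = a
                surviving: list[int] = []
                frag_marks = [k for k in marks if a <= positions[k] <= b]
                if cleaving_arm:
                    for k in frag_marks:  # ascending positions
                        if arm_rng.random() < cleave_p[k]:
                            start = positions[k] + 1  # excise base, drop 5' piece
                        else:
                            surviving.append(k)
                else:
                    surviving = frag_marks
                surviving = [k for k in surviving if positions[k] >= start]
                if cfg.rt_stop_prob > 0.0:
                    for k in surviving:
                        if arm_rng.random() < cfg.rt_stop_prob:
                            start = max(start, positions[k] + 1)
                if start > b:
                    continue  # nothing ligatable remains
                if not cfg.frag_min <= b - start + 1 <= cfg.frag_max:
                    continue
                end = b
                if cfg.max_read_length is not None:
                    end = min(b, start + cfg.max_read_length - 1)
                reads.append(ReadRecord(t.id, start, end))
    return reads


def simulate_experiment(
    transcripts: TranscriptSet,
    truth: ModificationTruth,
    config: SimulationConfig,
    *,
    require_c: bool = True,
) -> SimulatedExperiment:
    """Run the generative process for every arm and replicate.

    Deterministic given (inputs, seed); sample order is fixed as groups
    (Ctrl, HAC, DM-HAC) x replicates (1..R), molecules iterated in
    (transcript order, molecule index) order.
    """
    truth.validate(transcripts, require_c=require_c)
    reads: dict[SampleKey, list[ReadRecord]] = {}
    for group_idx, group in enumerate(GROUPS):
        for rep in range(1, config.replicates + 1):
            reads[(group, rep)] = _simulate_sample(
                group_idx, rep, transcripts, truth, config
            )
    return SimulatedExperiment(transcripts, truth, config, reads)


def write_reads_tsv(reads: Iterable[ReadRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.transcript_id, r.start, r.end) for r in reads],
        columns=["transcript_id", "start", "end"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_sam(
    reads: Iterable[ReadRecord], transcripts: TranscriptSet, path: str | Path
) -> None:
    """Write reads as forward-strand, fully-matched SAM alignments.

    Query sequences are emitted in the DNA alphabet (U -> T), matching
    sequencer output; the header carries one @SQ line per transcript.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in transcripts],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for idx, r in enumerate(reads):
            t = transcripts[r.transcript_id]
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"sim.{idx}"
            a.flag = 0
            a.reference_id = fh.header.get_tid(r.transcript_id)
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            length = r.end - r.start + 1
            a.cigartuples = [(0, length)]
            a.query_sequence = t.sequence[r.start - 1 : r.end].replace("U", "T")
            fh.write(a)
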