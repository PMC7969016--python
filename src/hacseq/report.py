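"""Summaries of called sites: motif windows, base composition, heat maps.

The sequence context of called sites is summarized as 7-nt windows
(3 nt either side of the site) tallied into a position x base count
matrix — the input one would hand to a logo tool.  Human m3C sites sit
in a conserved GGNCU context (G at -3/-2, U at +1), so a well-recovered
call set shows that consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hacseq.caller import SiteEvaluation, called_sites
from hacseq.coverage import GROUPS
from hacseq.refio import TranscriptSet

BASES = ("A", "C", "G", "U")


@dataclass
class MotifMatrix:
    """Window strings and per-offset base counts around called sites."""

    flank: int = 3
    windows: list[str] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    skipped: int = 0

    @property
    def width(self) -> int:
        return 2 * self.flank + 1

    def add(self, name: str, window: str) -> None:
        if len(window) != self.width:
            raise ValueError(
                f"window {window!r} has length {len(window)}, expected {self.width}"
            )
        self.names.append(name)
        self.windows.append(window)

    def counts(self) -> pd.DataFrame:
        """Base x offset count matrix; every offset column sums to the
        number of tallied windows."""
        offsets = list(range(-self.flank, self.flank + 1))
        data = {off: {b: 0 for b in BASES} for off in offsets}
        for w in self.windows:
            for off, ch in zip(offsets, w):
                if ch in data[off]:
                    data[off][ch] += 1
        frame = pd.DataFrame(
            {off: [data[off][b] for b in BASES] for off in offsets}, index=list(BASES)
        )
        frame.index.name = "base"
        return frame

    def consensus(self) -> str:
        """Most frequent base per offset (ties broken alphabetically)."""
        counts = self.counts()
        return "".join(counts[off].idxmax() for off in counts.columns)

    def write_counts_tsv(self, path: str | Path) -> None:
        self.counts().to_csv(path, sep="\t")

    def write_windows_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(w), id=name, description="")
            for name, w in zip(self.names, self.windows)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_windows_fasta(cls, path: str | Path, flank: int = 3) -> "MotifMatrix":
        m = cls(flank=flank)
        for rec in SeqIO.parse(str(path), "fasta"):
            m.add(rec.id, str(rec.seq))
        return m


def extract_motif_windows(
    evaluations: Sequence[SiteEvaluation],
    transcripts: TranscriptSet,
    flank: int = 3,
) -> MotifMatrix:
    """Collect flank-nt windows around every called site.

    Sites closer than ``flank`` to either transcript end are skipped
    (never padded — padding would misstate the frequencies) and counted
    in ``skipped``; skipped + tallied always equals the called total.
    """
    matrix = MotifMatrix(flank=flank)
    for e in called_sites(evaluations):
        t = transcripts[e.transcript_id]
        i = e.position
        if i - flank < 1 or i + flank > len(t):
            matrix.skipped += 1
            continue
        window = t.sequence[i - 1 - flank : i + flank]
        matrix.add(f"{e.transcript_id}:{i}", window)
    return matrix


def base_composition(evaluations: Sequence[SiteEvaluation]) -> dict[str, int]:
    """Called-site counts per reference base (the specificity readout:
    a clean run is all-C)."""
    counts = {b: 0 for b in BASES}
    for e in called_sites(evaluations):
        counts[e.ref_base] = counts.get(e.ref_base, 0) + 1
    return counts


def _site_label(e: SiteEvaluation) -> str:
    label = f"{e.transcript_id}:{e.position}"
    if e.label:
        label += f":{e.label}"
    return label


def heatmap_table(
    evaluations: Sequence[SiteEvaluation],
    site_subset: Iterable[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Mean cleavage ratio per site (rows) and arm (columns Ctrl, HAC,
    DM-HAC).  Defaults to called sites; ``site_subset`` selects explicit
    (transcript_id, position) rows regardless of call status."""
    if site_subset is None:
        chosen = called_sites(evaluations)
    else:
        wanted = list(site_subset)
        index = {(e.transcript_id, e.position): e for e in evaluations}
        missing = [key for key in wanted if key not in index]
        if missing:
            raise ValueError(f"sites not present in evaluations: {missing}")
        chosen = [index[key] for key in wanted]
    rows = {
        _site_label(e): [e.ctrl_mean, e.hac_mean, e.dmhac_mean] for e in chosen
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS))
    frame.index.name = "site"
    return frame


def write_base_composition_tsv(counts: dict[str, int], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"base": list(counts), "called_sites": [counts[b] for b in counts]}
    )
    frame.to_csv(path, sep="\t", index=False)


def write_reports(
    evaluations: Sequence[SiteEvaluation],
    transcripts: TranscriptSet,
    outdir: str | Path,
    flank: int = 3,
) -> MotifMatrix:
    """Write motif counts + windows, base composition and heat-map TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = extract_motif_windows(evaluations, transcripts, flank=flank)
    matrix.write_counts_tsv(outdir / "motif_counts.tsv")
    matrix.write_windows_fasta(outdir / "motif_windows.fasta")
    write_base_composition_tsv(
        base_composition(evaluations), outdir / "base_composition.tsv"
    )
    heatmap_table(evaluations).to_csv(outdir / "heatmap.tsv", sep="\t")
    return matrix
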