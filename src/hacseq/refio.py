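"""Transcript reference handling.

References for cleavage-ratio profiling are mature transcript sequences
(tRNAs, mRNAs, ncRNAs) stored in the RNA alphabet, optionally annotated
with structural position labels in Sprinzl-style numbering ("20", "32",
"47d", ...).  Because many tRNA genes encode byte-identical mature
sequences that short reads cannot distinguish, a :class:`TranscriptSet`
can collapse duplicates to a single representative while remembering the
removed ids in an alias map, so alignments against any gene copy still
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")


class Category(str, Enum):
    """Broad biotype of a reference transcript."""

    TRNA = "tRNA"
    MRNA = "mRNA"
    NCRNA = "ncRNA"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: "Category | str") -> "Category":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise ValueError(f"unknown transcript category {value!r}")


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase and convert DNA-style T to U; reject non-ACGUN characters.

    Raises ValueError naming the 1-based position of the first offending
    character.
    """
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        pos = next(i for i, ch in enumerate(seq, start=1) if ch in bad)
        raise ValueError(
            f"{context}: invalid character {seq[pos - 1]!r} at position {pos} "
            "(expected A/C/G/U/T/N)"
        )
    return seq


@dataclass
class Transcript:
    """One reference sequence with optional structural position labels.

    ``labels`` maps 1-based positions to field-standard structural names
    (e.g. 32 -> "32", 48 -> "47d"); every labelled position must lie
    inside the sequence.
    """

    id: str
    sequence: str
    category: Category = Category.OTHER
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        self.category = Category.coerce(self.category)
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: non-RNA characters {sorted(bad)!r} "
                "(normalize with normalize_sequence first)"
            )
        for pos in self.labels:
            self._check_position(pos)

    def _check_position(self, pos: int) -> None:
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(
                f"transcript {self.id!r}: position {pos} outside "
                f"1..{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        self._check_position(position)
        return self.sequence[position - 1]


class TranscriptSet:
    """Ordered collection of transcripts with unique ids and an alias map.

    The alias map records ids removed by :meth:`deduplicate` so that any
    name appearing in alignments can still be resolved to its surviving
    representative.
    """

    def __init__(
        self,
        transcripts: Iterable[Transcript] = (),
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self._by_id: dict[str, Transcript] = {}
        for t in transcripts:
            self.add(t)
        self.aliases: dict[str, str] = dict(aliases or {})

    def add(self, transcript: Transcript) -> None:
        if transcript.id in self._by_id:
            raise ValueError(f"duplicate transcript id {transcript.id!r}")
        self._by_id[transcript.id] = transcript

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, name: str) -> bool:
        return name in self._by_id or name in self.aliases

    def ids(self) -> list[str]:
        return list(self._by_id)

    def resolve(self, name: str) -> str:
        """Map any known id (surviving or collapsed) to its representative."""
        if name in self._by_id:
            return name
        if name in self.aliases:
            return self.aliases[name]
        raise KeyError(f"unknown transcript {name!r}")

    def __getitem__(self, name: str) -> Transcript:
        return self._by_id[self.resolve(name)]

    def deduplicate(self) -> "TranscriptSet":
        """Collapse byte-identical sequences onto the first-seen id.

        Survivor order follows input order; every removed id (and every
        pre-existing alias) maps to its representative in the new alias
        map.  Idempotent.
        """
        survivors: list[Transcript] = []
        by_seq: dict[str, str] = {}
        removed: dict[str, str] = {}
        for t in self._by_id.values():
            keeper = by_seq.get(t.sequence)
            if keeper is None:
                by_seq[t.sequence] = t.id
                survivors.append(t)
            else:
                removed[t.id] = keeper
        aliases = dict(removed)
        for old, target in self.aliases.items():
            aliases[old] = removed.get(target, target)
        return TranscriptSet(survivors, aliases)


def read_fasta(
    path: str | Path, category: Category | str = Category.OTHER
) -> TranscriptSet:
    """Load a (possibly multi-line) FASTA into a TranscriptSet.

    The id is the header up to the first whitespace (SAM reference-name
    compatible); sequences are normalized to the RNA alphabet.
    """
    category = Category.coerce(category)
    ts = TranscriptSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        ts.add(Transcript(rec.id, seq, category))
    return ts


def write_fasta(transcripts: TranscriptSet | Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts as FASTA, sequence lines wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_labels(path: str | Path, transcripts: TranscriptSet) -> TranscriptSet:
    """Attach structural position labels from a 3-column TSV.

    Columns: transcript_id, position (1-based), label.  Lines starting
    with '#' are comments; an optional literal header row is skipped.
    Rows naming unknown transcripts or out-of-range positions raise a
    ValueError citing the row number.  Returns the same set, mutated.
    """
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: row {row_no}: expected 3 tab-separated columns"
                )
            tid, pos_str, label = fields[0], fields[1], fields[2]
            if (tid, pos_str.lower()) == ("transcript_id", "position"):
                continue
            if tid not in transcripts:
                raise ValueError(
                    f"{path}: row {row_no}: unknown transcript {tid!r}"
                )
            try:
                pos = int(pos_str)
            except ValueError as err:
                raise ValueError(
                    f"{path}: row {row_no}: position {pos_str!r} is not an integer"
                ) from err
            t = transcripts[tid]
            if not 1 <= pos <= len(t):
                raise ValueError(
                    f"{path}: row {row_no}: position {pos} outside 1..{len(t)} "
                    f"for transcript {tid!r}"
                )
            t.labels[pos] = label
    return transcripts
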