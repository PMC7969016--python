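"""Synthetic tRNA reference panel with planted m3C sites.

Builds a fully synthetic stand-in for the human tRNA m3C target
repertoire: 13 modified species — the four serine isoacceptors carrying
both C32 (anticodon loop) and C47d (variable loop), two arginine and
three threonine isoacceptors plus two mitochondrial species at C32,
LeuCAG at C47d and MetCAT at C20 (D loop) — 17 sites in all, plus two
unmodified species as negative controls.  Sequences are random RNA of
tRNA-like length (85 nt for the long-variable-arm serine bodies, 76 nt
otherwise) with the conserved GGNCU-style context embedded at each
planted site; they are synthetic and correspond to no real gene.
"""

from __future__ import annotations

import numpy as np

from hacseq.refio import Category, Transcript, TranscriptSet
from hacseq.simulate import ModificationTruth, TruthSite

#: Structural label -> linear 1-based position in the synthetic bodies.
STRUCTURAL_POSITIONS = {"20": 20, "32": 32, "47d": 48}

#: (species name, structural labels of planted sites)
PANEL_LAYOUT: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("tRNA-SerAGA", ("32", "47d")),
    ("tRNA-SerCGA", ("32", "47d")),
    ("tRNA-SerGCT", ("32", "47d")),
    ("tRNA-SerTGA", ("32", "47d")),
    ("tRNA-ArgCCT", ("32",)),
    ("tRNA-ArgTCT", ("32",)),
    ("tRNA-ThrAGT", ("32",)),
    ("tRNA-ThrCGT", ("32",)),
    ("tRNA-ThrTGT", ("32",)),
    ("tRNA-LeuCAG", ("47d",)),
    ("tRNA-MetCAT", ("20",)),
    ("mt-tRNA-SerTGA", ("32",)),
    ("mt-tRNA-ThrTGT", ("32",)),
    ("tRNA-GlyGCC", ()),   # unmodified negative controls
    ("tRNA-ValCAC", ()),
)

#: Default 7-nt context planted around each site (offsets -3..+3; the
#: site cytidine at the center): matches the conserved G G N C U motif.
DEFAULT_CONTEXT = "GGACUAU"


def make_trna_panel(
    seed: int = 0,
    *,
    s_range: tuple[float, float] = (0.7, 1.0),
    demethylation: float = 1.0,
    context: str = DEFAULT_CONTEXT,
) -> tuple[TranscriptSet, ModificationTruth]:
    """Build the panel and its planted-site truth table.

    Site stoichiometries are spread deterministically (evenly) across
    ``s_range`` in site order; all sites share the given demethylation
    efficiency.  ``context`` must be a 7-mer with C at the center.
    """
    if len(context) != 7 or context[3] != "C":
        raise ValueError("context must be a 7-mer with C at offset 0 (index 3)")
    rng = np.random.default_rng(seed)
    transcripts = TranscriptSet()
    site_list: list[tuple[str, int]] = []
    for name, labels in PANEL_LAYOUT:
        length = 85 if "47d" in labels or "Ser" in name else 76
        seq = rng.choice(list("ACGU"), size=length)
        label_map: dict[int, str] = {}
        for lab in labels:
            pos = STRUCTURAL_POSITIONS[lab]
            seq[pos - 4 : pos + 3] = list(context)
            label_map[pos] = lab
            site_list.append((name, pos))
        transcripts.add(
            Transcript(name, "".join(seq), Category.TRNA, labels=label_map)
        )
    n_sites = len(site_list)
    stoich = np.linspace(s_range[0], s_range[1], n_sites)
    truth = ModificationTruth(
        TruthSite(tid, pos, float(s), demethylation)
        for (tid, pos), s in zip(site_list, stoich)
    )
    truth.validate(transcripts)
    return transcripts, truth
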