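"""Cleavage-ratio computation and three-criterion m3C site calling.

The core statistic at site i is the cleavage ratio

    r_i = starts[i+1] / depth[i+1]

— the fraction of reads covering position i+1 that begin exactly there.
Backbone cleavage at a modified base i excises the base and releases a
ligatable 3' fragment starting at i+1, so r_i estimates the fraction of
molecules cleaved at i (and, at maximal chemistry efficiency, the
modification stoichiometry).

A position is called modified when, across replicates:

  (i)   the mean cleavage ratio in the cleaved arm (HAC) reaches r_min
        (default 0.5);
  (ii)  the ratio rises at least fold_min-fold (default 2.5) over the
        untreated control with an unpaired two-sided Student's t-test
        below alpha (default 0.05);
  (iii) the ratio falls at least fold_min-fold when the RNA is
        demethylated before cleavage (DM-HAC), again significant.

Criterion (iii) is what makes the call methylation-specific: cleavage
that survives demethylase pre-treatment (AlkB-resistant positions) fails
it and is rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hacseq.coverage import GROUPS, CoverageProfile, SampleKey
from hacseq.refio import TranscriptSet


@dataclass
class CallingConfig:
    """Thresholds of the three-criterion calling procedure.

    min_depth is a coverage floor (default 20 reads at position i+1 in
    every sample) guarding against apparent cleavage in poorly covered
    regions; sites below it are reported as untestable rather than
    dropped.  base_filter restricts calls to reference cytidines;
    p_adjust switches the raw per-site p-values to Benjamini-Hochberg
    adjusted ones.
    """

    r_min: float = 0.5
    fold_min: float = 2.5
    alpha: float = 0.05
    min_depth: int = 20
    base_filter: bool = False
    p_adjust: str = "none"  # "none" | "BH"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min {self.r_min} outside [0, 1]")
        if self.fold_min < 1.0:
            raise ValueError(f"fold_min {self.fold_min} must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.p_adjust not in ("none", "BH"):
            raise ValueError(f"p_adjust must be 'none' or 'BH', got {self.p_adjust!r}")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CallingConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown calling config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class SiteEvaluation:
    """Full record of one candidate position (called or not).

    reason is "ok" for evaluable sites; untestable sites carry
    "low_depth", "N_base" or "non_C_base" and all criteria false.
    """

    transcript_id: str
    position: int
    ref_base: str
    label: str | None
    ctrl_ratios: tuple[float, ...]
    hac_ratios: tuple[float, ...]
    dmhac_ratios: tuple[float, ...]
    ctrl_mean: float
    hac_mean: float
    dmhac_mean: float
    fold_increase: float
    fold_decrease: float
    p_inc: float
    p_dec: float
    c1: bool
    c2: bool
    c3: bool
    called: bool
    reason: str
    min_depth_observed: int


def cleavage_ratio_profile(cov: CoverageProfile) -> np.ndarray:
    """Cleavage ratios for sites i = 1..L-1; NaN where depth[i+1] == 0.

    Element k (0-based) is the ratio at site i = k+1, computed from
    position i+1 of the profile.
    """
    if cov.length < 2:
        raise ValueError(f"{cov.transcript_id}: need length >= 2 for ratios")
    starts = cov.starts[1:].astype(float)
    depth = cov.depth[1:].astype(float)
    out = np.full(cov.length - 1, np.nan)
    np.divide(starts, depth, out=out, where=depth > 0)
    return out


def _pooled_t_pvalues(
    m1: np.ndarray, v1: np.ndarray, n1: int,
    m2: np.ndarray, v2: np.ndarray, n2: int,
) -> np.ndarray:
    """Two-sided pooled-variance (equal-variance) t-test, vectorized.

    Degenerate rules: zero pooled variance with different means -> p=0;
    with identical means -> p=1.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    zero_var = sp2 == 0
    return np.where(zero_var, np.where(m1 == m2, 1.0, 0.0), p)


def ttest_unpaired(a: Sequence[float], b: Sequence[float]) -> float:
    """Unpaired two-sided Student's t-test (pooled variance) p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("undefined ratios cannot be tested")
    p = _pooled_t_pvalues(
        a.mean(keepdims=True), a.var(ddof=1, keepdims=True), a.size,
        b.mean(keepdims=True), b.var(ddof=1, keepdims=True), b.size,
    )
    return float(p[0])


def band_cleavage_ratio(cleaved_intensity: float, uncleaved_intensity: float) -> float:
    """Gel-band analogue of the statistic: cleaved / (cleaved + uncleaved)."""
    if cleaved_intensity < 0 or uncleaved_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = cleaved_intensity + uncleaved_intensity
    if total == 0:
        raise ValueError("no signal: both band intensities are zero")
    return cleaved_intensity / total


def _check_structure(
    profiles: Mapping[SampleKey, Mapping[str, CoverageProfile]]
) -> list[int]:
    groups = {g for g, _ in profiles}
    missing = set(GROUPS) - groups
    if missing:
        raise ValueError(f"missing group(s) {sorted(missing)}")
    extra = groups - set(GROUPS)
    if extra:
        raise ValueError(f"unknown group(s) {sorted(extra)}")
    reps_by_group = {g: sorted(r for g2, r in profiles if g2 == g) for g in GROUPS}
    reps = reps_by_group[GROUPS[0]]
    if any(reps_by_group[g] != reps for g in GROUPS):
        raise ValueError(f"unequal replicate structure: {reps_by_group}")
    if len(reps) < 2:
        raise ValueError("at least 2 replicates per group are required")
    return reps


def call_sites(
    profiles: Mapping[SampleKey, Mapping[str, CoverageProfile]],
    config: CallingConfig,
    transcripts: TranscriptSet,
) -> list[SiteEvaluation]:
    """Evaluate every position i = 1..L-1 of every transcript.

    ``profiles`` maps (group, replicate) -> {transcript_id -> profile};
    all three groups must be present with equal replicate sets (>= 2).
    Fold changes compare means of per-replicate ratios; a zero
    denominator with a positive numerator passes the fold component (the
    ideal positive: no background cleavage at all).  Every position is
    returned — called, rejected, or untestable with a reason code —
    sorted by transcript input order then position.
    """
    reps = _check_structure(profiles)
    n = len(reps)

    per_transcript: list[dict] = []
    all_p_inc: list[np.ndarray] = []
    all_p_dec: list[np.ndarray] = []

    for t in transcripts:
        if len(t) < 2:
            continue
        ratio = {}
        depth_stack = []
        for g in GROUPS:
            rows = []
            for r in reps:
                try:
                    prof = profiles[(g, r)][t.id]
                except KeyError as err:
                    raise ValueError(
                        f"sample ({g}, rep {r}) lacks transcript {t.id!r}"
                    ) from err
                rows.append(cleavage_ratio_profile(prof))
                depth_stack.append(prof.depth[1:])
            ratio[g] = np.vstack(rows)
        depth_min = np.min(np.vstack(depth_stack), axis=0)

        bases = np.frombuffer(t.sequence.encode(), dtype="S1")[:-1].astype("U1")
        evaluable = depth_min >= config.min_depth
        reason = np.where(evaluable, "ok", "low_depth").astype(object)
        n_mask = evaluable & (bases == "N")
        reason[n_mask] = "N_base"
        evaluable &= ~n_mask
        if config.base_filter:
            non_c = evaluable & (bases != "C")
            reason[non_c] = "non_C_base"
            evaluable &= ~non_c

        means = {g: ratio[g].mean(axis=0) for g in GROUPS}
        variances = {g: ratio[g].var(axis=0, ddof=1) for g in GROUPS}
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_inc = means["HAC"] / means["Ctrl"]
            fold_dec = means["HAC"] / means["DM-HAC"]
        p_inc = _pooled_t_pvalues(
            means["HAC"], variances["HAC"], n, means["Ctrl"], variances["Ctrl"], n
        )
        p_dec = _pooled_t_pvalues(
            means["HAC"], variances["HAC"], n,
            means["DM-HAC"], variances["DM-HAC"], n,
        )
        per_transcript.append(
            dict(
                transcript=t, ratio=ratio, means=means, bases=bases,
                depth_min=depth_min, evaluable=evaluable, reason=reason,
                fold_inc=fold_inc, fold_dec=fold_dec, p_inc=p_inc, p_dec=p_dec,
            )
        )
        all_p_inc.append(p_inc[evaluable])
        all_p_dec.append(p_dec[evaluable])

    if config.p_adjust == "BH":
        from statsmodels.stats.multitest import multipletests

        for which, collected in (("p_inc", all_p_inc), ("p_dec", all_p_dec)):
            flat = np.concatenate(collected) if collected else np.array([])
            if flat.size:
                adjusted = multipletests(flat, method="fdr_bh")[1]
                offset = 0
                for rec in per_transcript:
                    mask = rec["evaluable"]
                    k = int(mask.sum())
                    vals = rec[which].copy()
                    vals[mask] = adjusted[offset : offset + k]
                    rec[which] = vals
                    offset += k

    evaluations: list[SiteEvaluation] = []
    for rec in per_transcript:
        t = rec["transcript"]
        means = rec["means"]
        # fold component: >= fold_min, with inf (0 denominator, positive
        # numerator) passing and NaN (0/0) failing by comparison semantics
        c1 = means["HAC"] >= config.r_min
        with np.errstate(invalid="ignore"):
            c2 = (rec["fold_inc"] >= config.fold_min) & (rec["p_inc"] < config.alpha)
            c3 = (rec["fold_dec"] >= config.fold_min) & (rec["p_dec"] < config.alpha)
        ev = rec["evaluable"]
        c1, c2, c3 = c1 & ev, c2 & ev, c3 & ev
        called = c1 & c2 & c3
        for k in range(len(t) - 1):
            i = k + 1
            usable = bool(ev[k])
            evaluations.append(
                SiteEvaluation(
                    transcript_id=t.id,
                    position=i,
                    ref_base=str(rec["bases"][k]),
                    label=t.labels.get(i),
                    ctrl_ratios=tuple(float(x) for x in rec["ratio"]["Ctrl"][:, k]),
                    hac_ratios=tuple(float(x) for x in rec["ratio"]["HAC"][:, k]),
                    dmhac_ratios=tuple(float(x) for x in rec["ratio"]["DM-HAC"][:, k]),
                    ctrl_mean=float(means["Ctrl"][k]),
                    hac_mean=float(means["HAC"][k]),
                    dmhac_mean=float(means["DM-HAC"][k]),
                    fold_increase=float(rec["fold_inc"][k]),
                    fold_decrease=float(rec["fold_dec"][k]),
                    p_inc=float(rec["p_inc"][k]) if usable else float("nan"),
                    p_dec=float(rec["p_dec"][k]) if usable else float("nan"),
                    c1=bool(c1[k]),
                    c2=bool(c2[k]),
                    c3=bool(c3[k]),
                    called=bool(called[k]),
                    reason=str(rec["reason"][k]),
                    min_depth_observed=int(rec["depth_min"][k]),
                )
            )
    return evaluations


def called_sites(evaluations: Sequence[SiteEvaluation]) -> list[SiteEvaluation]:
    return [e for e in evaluations if e.called]


def evaluations_to_frame(evaluations: Sequence[SiteEvaluation]) -> pd.DataFrame:
    """Flatten evaluations to a table; replicate ratios are comma-joined."""
    rows = []
    for e in evaluations:
        rows.append(
            {
                "transcript_id": e.transcript_id,
                "position": e.position,
                "ref_base": e.ref_base,
                "label": "" if e.label is None else e.label,
                "ctrl_ratios": ",".join(repr(float(x)) for x in e.ctrl_ratios),
                "hac_ratios": ",".join(repr(float(x)) for x in e.hac_ratios),
                "dmhac_ratios": ",".join(repr(float(x)) for x in e.dmhac_ratios),
                "ctrl_mean": e.ctrl_mean,
                "hac_mean": e.hac_mean,
                "dmhac_mean": e.dmhac_mean,
                "fold_increase": e.fold_increase,
                "fold_decrease": e.fold_decrease,
                "p_inc": e.p_inc,
                "p_dec": e.p_dec,
                "c1": e.c1,
                "c2": e.c2,
                "c3": e.c3,
                "called": e.called,
                "reason": e.reason,
                "min_depth_observed": e.min_depth_observed,
            }
        )
    columns = [
        "transcript_id", "position", "ref_base", "label",
        "ctrl_ratios", "hac_ratios", "dmhac_ratios",
        "ctrl_mean", "hac_mean", "dmhac_mean",
        "fold_increase", "fold_decrease", "p_inc", "p_dec",
        "c1", "c2", "c3", "called", "reason", "min_depth_observed",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_calls_tsv(evaluations: Sequence[SiteEvaluation], path: str | Path) -> None:
    evaluations_to_frame(evaluations).to_csv(path, sep="\t", index=False, na_rep="nan")


def _parse_ratio_tuple(text: str) -> tuple[float, ...]:
    if not isinstance(text, str) or not text:
        return ()
    return tuple(float(x) for x in text.split(","))


def read_calls_tsv(path: str | Path) -> list[SiteEvaluation]:
    """Reload a calls table written by :func:`write_calls_tsv`."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan"])
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SiteEvaluation(
                transcript_id=str(row.transcript_id),
                position=int(row.position),
                ref_base=str(row.ref_base),
                label=str(row.label) or None,
                ctrl_ratios=_parse_ratio_tuple(row.ctrl_ratios),
                hac_ratios=_parse_ratio_tuple(row.hac_ratios),
                dmhac_ratios=_parse_ratio_tuple(row.dmhac_ratios),
                ctrl_mean=float(row.ctrl_mean),
                hac_mean=float(row.hac_mean),
                dmhac_mean=float(row.dmhac_mean),
                fold_increase=float(row.fold_increase),
                fold_decrease=float(row.fold_decrease),
                p_inc=float(row.p_inc),
                p_dec=float(row.p_dec),
                c1=bool(row.c1),
                c2=bool(row.c2),
                c3=bool(row.c3),
                called=bool(row.called),
                reason=str(row.reason),
                min_depth_observed=int(row.min_depth_observed),
            )
        )
    return out


def write_bed(evaluations: Sequence[SiteEvaluation], path: str | Path) -> None:
    """Called sites as BED6 (0-based half-open; score = mean HAC ratio
    x1000 capped at 1000; strand '+')."""
    with open(path, "w") as fh:
        for e in called_sites(evaluations):
            name = f"{e.transcript_id}:{e.position}"
            if e.label:
                name += f":{e.label}"
            score = min(1000, int(round(e.hac_mean * 1000)))
            fh.write(
                f"{e.transcript_id}\t{e.position - 1}\t{e.position}\t"
                f"{name}\t{score}\t+\n"
            )
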