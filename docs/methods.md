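# Methods

## The measurement model

Hydrazine (in 3 M NaCl) adds specifically to 3-methylcytidine; aniline
then cleaves the backbone at the adduct. Cleavage excises the modified
base: the 3′ product begins one base 3′ of the site and carries a clean
5′ phosphate, while the 5′ product has a damaged 3′ end and is lost at
adapter ligation. In sequencing data, cleavage at position *i* is
therefore visible only as an excess of reads starting at *i* + 1.

The per-site statistic is the cleavage ratio
`r_i = starts[i+1] / depth[i+1]`, defined for *i* = 1..L−1 and
undefined (not zero, not an error) where `depth[i+1] = 0`. Because a
read starting at *i* + 1 also covers *i* + 1, `r_i ∈ [0, 1]` wherever
defined.

Three arms give the contrast that makes a ratio peak a modification
call: Ctrl (no cleavage — background read starts come from
fragmentation), HAC (cleavage), DM-HAC (demethylated before cleavage —
methylation-dependent peaks collapse). A position is called when the
HAC ratio is high in absolute terms (criterion i), elevated over Ctrl
(ii), and demethylase-sensitive (iii). Criterion (iii) is the
specificity filter: strong reproducible cleavage that AlkB cannot erase
(observed in cells at C32 of serine isoacceptors with A36, likely a
structural effect on enzyme access) is deliberately rejected.

## Calling procedure: definitions under test

The literature description of this method leaves several operational
details open; this package fixes them as follows and treats them as the
tested definitions:

- **Test operand.** The unpaired two-sided Student's *t*-test (pooled
  variance) is applied to per-replicate cleavage ratios, not raw
  counts. Degenerate inputs follow explicit rules: zero pooled variance
  with different means → *P* = 0; all values identical → *P* = 1.
- **Fold changes** compare means of per-replicate ratios. A zero
  denominator with a positive numerator passes the fold component (a
  site absent in the control is the ideal positive); 0/0 fails it.
- **Thresholds are inclusive** (≥ 0.5, ≥ 2.5-fold); *P* comparisons are
  strict (< α).
- **Read depth** is coverage by aligned reads: from SAM, depth accrues
  over reference-consumed aligned blocks (standard pileup semantics, so
  deletions/splices leave gaps); from the aligner-free TSV path, over
  the full start–end span. The two agree for fully-matched alignments
  such as the simulator's.
- **Coverage floor.** `min_depth` (default 20 reads at *i* + 1 in every
  sample) is an addition motivated by false positives arising in
  low-coverage regions; failing positions are reported with reason
  `low_depth`, never silently dropped. Positions at reference N are
  never callable.
- **Multiple testing.** Raw *P* < 0.05 by default, matching common
  practice for this assay; Benjamini–Hochberg adjustment (applied
  separately to the HAC-vs-Ctrl and HAC-vs-DM-HAC families over all
  evaluable sites of a run) is available as `p_adjust: BH`.
- **All four bases are evaluable** by default — the base composition of
  calls is itself the specificity readout; `base_filter` restricts
  calls to cytidines when wanted.
- Replicate structure must be complete: all three arms with the same
  replicate indices, at least two replicates per arm.

## Reference handling

Sequences are normalized to the RNA alphabet (T → U; N allowed, never
callable). Ids are the FASTA header up to the first whitespace, for SAM
compatibility. Because many tRNA genes share one mature sequence,
byte-identical sequences are collapsed to the first-seen id before
counting; an alias map keeps every removed id resolvable, so alignments
against any gene copy are credited to the representative. This reports
per unique mature sequence rather than per gene copy — reads cannot
distinguish the copies, so per-gene reporting would be arbitrary.
Structural labels ("20", "32", "47d") attach to 1-based positions via a
3-column TSV and propagate into call tables, BED names and heat-map row
labels.

## The simulator

Each molecule is played through the library chemistry in order:
stochastic marking of planted sites (per-site stoichiometry `s`) →
arm-specific demethylation (per-site efficiency `d`, DM-HAC only) →
random fragmentation (independent per-bond break probability λ, all
fragment ends repaired) → cleavage in HAC/DM-HAC (per still-marked site
with efficiency `c`, excising the base and discarding everything 5′,
so the surviving piece begins one base 3′ of the 3′-most realized
cleavage — which is why a 5′ site's ratio denominator excludes
molecules cleaved at a downstream site) → pre-library demethylation of
surviving marks, which with probability ε instead truncates the read at
the mark (residual RT hard stop) → size selection to
[`frag_min`, `frag_max`].

Closed forms used as oracles: with λ = 0 and a single planted site the
HAC-arm ratio at the site equals `s·c` in expectation (exactly 1 at
`s = c = 1`), with binomial error `sqrt(s·c(1−s·c)/N)`; the expected
ratio is monotone in `s` and `c` and the DM-HAC ratio non-increasing in
`d`.

Defaults and their reasoning:

| parameter | default | why |
|---|---|---|
| replicates | 2 | two biological replicates per arm, as in the assay's standard design |
| molecules/transcript/replicate | 1000 | gives site depths well above `min_depth` at tRNA length without slowing tests |
| break_prob λ | 0.005 /bond | mean fragment ≈ 200 nt for long RNAs; tRNA-length molecules mostly stay intact |
| cleavage c | 1.0 | the chemistry is run to maximal cleavage (4 h time point) |
| rt_stop_prob ε | 0.0 | the protocol demethylates before library prep; ε > 0 exists to stress criterion (iii) |
| size window | [15, 300] nt | small-RNA library size selection |

RNG: pre-cleavage draws (marking, fragmentation) come from a stream
keyed by (seed, replicate, transcript) shared across arms, with a
constant draw count per molecule; arm-specific draws (demethylation,
cleavage, ε) from a stream keyed by (seed, arm, replicate, transcript).
Consequences: identical (inputs, seed) ⇒ byte-identical outputs; `s=0`
⇒ cleaved arms equal Ctrl read-for-read; `d=1`, ε=0 ⇒ DM-HAC equals
Ctrl read-for-read (demethylation draws are then deterministic). SAM
output is forward-strand, fully-matched CIGAR, DNA-alphabet query
sequences, header limited to @HD/@SQ so outputs are reproducible
byte-for-byte.

What the simulator deliberately omits: sequencing errors and quality
scores, adapters, PCR duplication, rRNA contamination, alignment
ambiguity beyond identical-sequence collapse, ligation and RT sequence
biases, and coverage heterogeneity across transcripts. Passing tests on
simulated data therefore demonstrate the statistical and algorithmic
correctness of the pipeline under the stated generative model — not
robustness to real-library artifacts such as biased fragmentation or
mis-mapping.

## The synthetic tRNA panel

`hacseq.panel.make_trna_panel` builds a 15-transcript panel mirroring
the typical human m³C target layout: four serine isoacceptors with both
C32 and C47d, two arginine + three threonine + two mitochondrial
species at C32, LeuCAG at C47d, MetCAT at C20 — 17 sites — plus two
unmodified negatives. Sequences are random RNA (85 nt for the serine
bodies with their long variable arm, 76 nt otherwise; C47d mapped to
linear position 48) with the conserved GGNCU-style 7-mer context
(default `GGACUAU`) embedded at each site; they are synthetic and match
no real gene. Site stoichiometries are spread evenly across the
requested range (default 0.7–1.0, the high-stoichiometry regime where
the calling criteria should recover every site).

## Numerical and formatting choices

- Undefined ratios are NaN; NaN fails every criterion comparison, so
  untestable positions can never be called.
- Motif windows near transcript ends are skipped and counted, never
  N-padded (padding would misstate frequencies); consensus ties break
  alphabetically.
- BED output converts to 0-based half-open coordinates at the boundary
  only; score = mean HAC ratio × 1000, capped at 1000.
- Calls tables serialize replicate ratios with full float precision
  (`repr`) so a written/reloaded table is numerically identical.
- Problem sizes in the test and acceptance runs (400–3000 molecules per
  transcript and replicate, 5000 for the closed-form checks) are chosen
  so binomial noise is far from the decision thresholds while runs stay
  light-weight.

## Known limitations

- Cleavage ratios are semi-quantitative: with two sites on one
  transcript the upstream site's denominator is conditioned on no
  downstream cleavage, and absolute stoichiometry calibration against
  spiked standards is out of scope.
- No mismatch/misincorporation-based detection (ARM-seq / HAMR /
  modification-index approaches) — this package implements the
  cleavage-ratio method only.
- Multi-mapping reads beyond identical-sequence collapse are counted by
  their primary alignment only; no fractional assignment.
- The untreated-control arm shares the fragmentation model with the
  treated arms; chemistry-specific background (e.g. weak hydrazine
  reactivity at unmodified U under imperfect salt) is not modelled.
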