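# hacseq

Single-nucleotide calling of 3-methylcytidine (m³C) RNA modification
from hydrazine–aniline cleavage sequencing libraries.

m³C is a methyl mark on the Watson–Crick face of cytidine, found mainly
at structural positions C32 (anticodon loop), C47d (variable loop) and
C20 (D loop) of tRNAs. Under high-salt conditions hydrazine attacks m³C
specifically and aniline then cleaves the RNA backbone at the modified
base. The 3′ cleavage fragment keeps a ligatable 5′ phosphate while the
5′ fragment is left with a damaged 3′ end that cannot be
adapter-ligated, so after library preparation only full-length fragments
and 3′ cleavage products are sequenced. Cleavage at position *i*
therefore shows up as reads that begin exactly at *i* + 1.

This package is for epitranscriptomics analysts who have (or want to
simulate) such three-arm libraries — untreated control (**Ctrl**),
chemically cleaved (**HAC**), and demethylated-then-cleaved
(**DM-HAC**) — aligned to transcript references, and who want site-level
m³C calls with replicate statistics.

## The statistic and the calling rule

For each transcript position *i* the **cleavage ratio** is

```
r_i = starts[i+1] / depth[i+1]
```

the fraction of reads covering position *i* + 1 that start exactly
there. At maximal chemistry efficiency `r_i` approximates the fraction
of molecules cleaved — i.e. the modification stoichiometry at *i*.

Position *i* is called m³C when, across replicates:

1. mean HAC cleavage ratio ≥ `r_min` (default **0.5**);
2. ≥ `fold_min`-fold (default **2.5×**) increase HAC vs Ctrl, with
   two-sided unpaired Student's *t* (pooled variance) *P* < `alpha`
   (default **0.05**);
3. ≥ `fold_min`-fold decrease HAC vs DM-HAC, again significant —
   cleavage that survives AlkB demethylase pre-treatment is not
   methylation and is rejected here.

A configurable coverage floor (`min_depth`, default 20 reads at
*i* + 1 in every sample) marks poorly covered positions untestable
instead of calling them; all thresholds live in `CallingConfig` and the
YAML config.

The package also contains a generative simulator of the chemistry
(random fragmentation, end repair, per-site stoichiometry and cleavage
efficiency, loss of 5′ fragments, arm-specific demethylation, size
selection), a synthetic 17-site tRNA panel mirroring the typical human
m³C target layout, and reporting (7-nt motif windows and count matrix,
base composition, per-arm heat-map tables, BED output).

## Worked example

```python
from hacseq import (SimulationConfig, CallingConfig, simulate_experiment,
                    count_reads, call_sites, called_sites,
                    extract_motif_windows, base_composition)
from hacseq.panel import make_trna_panel

ts, truth = make_trna_panel(seed=0, s_range=(0.75, 1.0))   # 15 refs, 17 sites
cfg = SimulationConfig(seed=7, replicates=2, molecules=1000)
exp = simulate_experiment(ts, truth, cfg)
profiles = {k: count_reads(v, ts, group=k[0], replicate=k[1])
            for k, v in exp.reads.items()}
evals = call_sites(profiles, CallingConfig(), ts)
hits = called_sites(evals)
print(f"called {len(hits)} of {len(truth)} planted sites on {len(ts)} references")
e = next(x for x in hits if x.transcript_id == "tRNA-SerGCT" and x.position == 32)
print(f"{e.transcript_id} C{e.position}: HAC={e.hac_mean:.3f} "
      f"Ctrl={e.ctrl_mean:.3f} DM-HAC={e.dmhac_mean:.3f}")
print("consensus:", extract_motif_windows(evals, ts).consensus(),
      "| base composition:", base_composition(evals))
```

prints

```
called 17 of 17 planted sites on 15 references
tRNA-SerGCT C32: HAC=0.787 Ctrl=0.004 DM-HAC=0.004
consensus: GGACUAU | base composition: {'A': 0, 'C': 17, 'G': 0, 'U': 0}
```

All 17 planted sites — and nothing else — pass the three criteria: the
HAC arm cleaves ~79% of molecules at SerGCT C32 (planted stoichiometry
0.81 in this panel, estimated within binomial error) while background
read starts in Ctrl sit at the
fragmentation rate, and full demethylation returns DM-HAC to control
levels. Every call is at a cytidine and the consensus of the 7-nt
windows is the planted GGNCU-style context.

The same pipeline is available from the shell:

```sh
hacseq run --fasta refs.fasta --truth truth.tsv --labels labels.tsv \
           --config config.yaml --seed 7 --outdir out/
```

which writes per-sample reads (TSV/SAM), coverage tables, `calls.tsv` /
`calls.bed`, and the motif/composition/heat-map reports. `hacseq
simulate|count|call|report` run the stages separately on real or
simulated inputs (sample sheet: `file`, `group` ∈ {Ctrl, HAC, DM-HAC},
`replicate`).

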