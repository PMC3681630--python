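# trimfold

Processing pipeline for single-channel spotted microarrays in which every
gene is printed as **five identical replicate probes** and each condition is
a single pooled hybridization — the design used for genome-wide bacterial
stress-response profiling (the bundled synthetic design emulates a
5,003-gene *Clostridium beijerinckii* NCIMB 8052 array under furfural
challenge, with one control/treatment array pair per growth phase).

For users who have spot-level median intensities (native TSV or a
GenePix-style spot file) and want the classic bespoke analysis chain,
implemented with tests:

1. **Scale-factor normalization** — `SF = μ_control / μ_treatment` over the
   spot means; every treatment spot is multiplied by SF.
2. **Trimmed-mean summarization** — per gene and array, discard one maximum
   and one minimum adjusted signal of the five replicates, average the
   remaining three.
3. **Signed fold changes** — ratio `r = treatment/control`; fold = `r` if
   `r ≥ 1`, else `−1/r`, so |fold| ≥ 1 and repression reads −k-fold;
   DE calls at a strict > 3-fold threshold (no p-values: one pooled array
   per condition has no replicate variance).
4. **Term over-representation** — upper hypergeometric tail
   `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, optionally the conservative EASE
   variant (k−1), with Benjamini–Hochberg adjustment.
5. **Comparative-CT qPCR validation** — `ΔΔCT`-based relative expression
   `2^−ΔΔCT` against a constant reference gene (16S rRNA in the emulated
   design), and microarray↔qPCR Pearson concordance R.

A first-class synthetic-data generator (`trimfold.simulate`) produces
probe-level tables, term annotations and qPCR plates with recorded ground
truth, so the whole analysis runs and is tested without any external data.

## Worked example

```
$ trimfold run-all --seed 1 --outdir demo
acidogenic: SF=1.0851 up=53 down=56 R=0.9870
solventogenic: SF=0.3869 up=269 down=362 R=0.9380
summary written to demo/summary.json
```

This simulates the default design (5,003 genes × 5 probes × 4 arrays,
~110 / ~720 genes spiked DE in the two phases), normalizes, summarizes,
calls DE, tests term enrichment and runs the qPCR branch.  The beginning of
`demo/report.txt`:

```
[acidogenic]
  scale factor: 1.085072
  genes summarized: 5003
  genes with defined ratio: 5003
  up-regulated (> 3-fold): 53
  down-regulated: 56
  enriched terms (BH <= 0.05): 4
    T005  k=26/K=69  p=0.000e+00  adj=0.000e+00
    ...
  microarray-qPCR concordance R = 0.9870 (n = 19)
```

Reading the numbers: the acidogenic treatment slide was simulated 0.8× off
scale, and the fitted SF (1.085) differs from the ideal 1.25 because the
spot-mean is intensity-weighted and the spiked DE genes pull on it.  Of the
110 spiked genes, 106 are recalled at the strict 3-fold threshold (spikes
start at exactly 3-fold, so boundary spikes can land under threshold after
noise; 3 of the 109 calls are false positives); 4 of the 5 spiked
annotation terms reach BH ≤ 0.05; and the
19-gene qPCR panel correlates with the array folds at R = 0.987.  The
solventogenic phase, with 14% of genes DE up to 54-fold, shows the known
bias of mean-based normalization (SF 0.387 vs ideal 0.8) — see
`docs/methods.md`.

Each stage is also available separately (`simulate`, `preprocess`, `de`,
`enrich`, `qpcr`, `report`) against the same `--outdir`, and as library
functions (`trimfold.preprocess`, `trimfold.diffexpr`, `trimfold.enrichment`,
`trimfold.qpcr`).

## Applying it to real spot files

`trimfold.array_io.read_probe_table(path, dialect="gpr_subset",
id_column=..., signal_column=...)` reads a GenePix-style tab-delimited spot
file (header located by name, ATF preamble skipped), assigns replicate
indices by order of appearance of repeated ids, and rejects genes with
fewer than three spots.  Readers fail loudly on malformed input, naming the
offending line.
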