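# epitopescan

Autoantibody epitope discovery on high-density tiled peptide microarrays,
with an application profile modelled on membranous nephropathy (MN)
serology: proteome-wide arrays of overlapping 16-mer peptides (stride 3;
stride 1 for high-resolution antigens such as PLA2R1) are probed with
patient and control sera, and the pipeline extracts the peptides most
likely to be true antibody epitopes, relates peptide reactivity to clinical
traits such as proteinuria, and evaluates candidate antigens with
validation-array and ELISA-style statistics.

The package is aimed at computational immunologists and nephrology
researchers who have peptide-level fluorescence tables and want a tested,
scriptable implementation of this analysis rather than a collection of
one-off notebooks.

## What it computes

**S-PIE scan statistic.** A true epitope lights up a *run* of
tiling-adjacent peptides, because consecutive probes share the recognised
residues. For a fluorescence cut-off `I0`, with `P = P(I > I0)` estimated
from all measured intensities of a sample, the statistic is

```
R = P(I_a ... I_n all > I0) / [ P(I_a) ... P(I_n) ]
```

the ratio of the empirical probability that `N` consecutive peptides all
exceed the cut-off to its value under independence. The scan repeats over
an increasing grid of cut-offs (per-sample intensity quantiles), assigns R
to every peptide of each qualifying run, and keeps the latest value.
Peptides with `R > 1e6` in a case sample and in no control are hits;
low-complexity sequences (Shannon entropy < 3.17 bits) are then discarded.

**Co-expression module/trait stage.** A weighted network over peptide
profiles (`a_ij = |cor|^beta` with beta chosen by the scale-free topology
fit), topological overlap, average-linkage module detection with a minimum
of 30 peptides per module, module eigengenes, and Spearman module-trait
correlations with Benjamini-Hochberg correction.

**Validation-array statistics.** Classical MDS on Spearman dissimilarity,
Welch t-tests with BH adjustment and a fold-change threshold (volcano),
ANOVA-ranked linear-SVM peptide ranking with repeated 65/35 splits and
4-fold cross-validation, PLS-DA VIP scores, combined hit-set accounting,
and peptide-to-protein rollup.

**Serology statistics.** Mann-Whitney / Kruskal-Wallis with Dunn's
post-hoc, empirical ROC with Youden cutoff and likelihood ratio, and the
2x2 odds ratio linking a titer threshold to remission.

A synthetic-data generator (`epitopescan.simulate`) produces proteomes,
arrays with planted epitope runs, trait-coupled module structure and titer
tables, so the entire pipeline is testable without any array data.

## Worked example

```python
import epitopescan as es

cfg = es.SimulationConfig(seed=1, n_proteins=300, protein_length=(150, 250))
records = es.generate_proteome(cfg)
library = es.tile_proteome(records, k=16, step=3)        # 16-mers, stride 3
matrix, metadata, truth = es.simulate_array(library, cfg)

result = es.compute_spie(matrix, library)
hits = es.select_spie_hits(result, metadata)
print(len(library), int(hits["hit"].sum()), truth.peptide_rows().size)
```

prints

```
18674 15 15
```

i.e. a library of 18,674 tiled peptides in which the scan recovers exactly
the 15 peptides belonging to the three planted epitope runs (10 case and 4
control samples, multiplicative effect 100) with no false positives. The
same objects feed the downstream stages, e.g.
`es.filter_low_complexity(...)` for the entropy filter or
`es.fit_coexpression(...)` for the module/trait analysis.

The same workflow is available from the shell:

```
epitopescan simulate --seed 1 --out-dir data/
epitopescan spie --intensities data/intensities.tsv --metadata data/metadata.csv --out hits.tsv
epitopescan sero --table data/serology.csv --roc MN --out sero.json
```

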