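# bcelldev

Immunoglobulin repertoire analysis of early human B-cell development.

During B-cell maturation — large pre-B and immature cells in the bone
marrow, transitional and naive cells in peripheral blood — tolerance
checkpoints reshape the antibody repertoire. Because these populations
are antigen-naive, the repertoire differences between them read out the
*central selection* acting on newly formed receptors rather than any
antigen response. `bcelldev` implements the computational side of that
analysis for researchers working with annotated V(D)J rearrangement
tables (AIRR-style TSV, or IMGT/HighV-QUEST summary output): repertoire
cleanup, PCR-duplicate collapse, CDR3 physicochemical characterization,
gene-usage statistics, and multivariate subset discrimination — together
with a repertoire simulator that provides ground truth for every stage.

## What it computes

**Cleanup and duplicate collapse.** Reads are filtered to CDR3 lengths
within the normal windows (1–35 aa heavy chain, 1–20 aa light chain) and,
for peptide-level analyses, to productive rearrangements. Since naive
populations contain no clonal expansions, reads sharing a CDR3 are
treated as PCR duplicates: reads are single-linkage clustered on CDR3
nucleotide Levenshtein distance (default threshold 1, threshold 0 =
exact-match collapse) within each donor × subset × chain × V × J group,
and each cluster is reduced to a modal representative sequence.

**CDR3 descriptors.** For each unique rearrangement: length, GRAVY
(mean Kyte–Doolittle hydropathy), Boman index, molecular weight,
isoelectric point (Henderson–Hasselbalch net charge, bisection root),
aliphatic index, nine amino-acid class counts, and the mean of the ten
Kidera factors KF1–KF10 (orthogonal scales summarizing ~140 residue
properties).

**Statistics.** Per-donor gene/family usage frequencies (percent of
unique clonotypes) and VDJ/VJ family-combination tensors; subset
comparisons by two-way ANOVA with Holm–Šidák-adjusted per-key contrasts,
paired Wilcoxon or Mann–Whitney tests; and for CDR3 properties a
Gaussian random-intercept mixed model, `property ~ subset + (1|donor)`,
fitted by ML with a likelihood-ratio test against the donor-only null.

**Multivariate.** Per-donor feature means are analysed by PCA (with a
label-permutation control that reruns the whole donor-means → PCA
pipeline to ask whether subset separation exceeds chance) and by
agglomerative clustering under the Minkowski power-4 distance, exported
as Newick dendrograms.

**Simulator.** `bcelldev.simulate` generates annotated repertoires with
subset-specific family-usage shifts planted at realistic magnitudes
(e.g. a 14-point IGHV3 drop from pre-B to naive, a 9.5-point IGHJ6
excess in transitional cells), developmental CDR3-length shrinkage with
an age interaction, junctional trimming/N-insertion, PCR duplication,
and per-base sequencing error — with per-read ground truth.

## Worked example

```python
from bcelldev import (SimulationConfig, simulate_repertoire, apply_filters,
                      cluster_duplicates, usage_frequencies, compare_usage)

cfg = SimulationConfig(n_donors=5, clonotypes_per_subset=2000, seed=1)
sim = simulate_repertoire(cfg, chain="IGH")
print(f"{len(sim.records)} reads, {sim.truth.n_true_clonotypes} true clonotypes")

kept, removed = apply_filters(sim.records, stage="gene_stage")
clonotypes = cluster_duplicates(kept, threshold=1)
print(f"{len(clonotypes)} unique rearrangements after dedup")

table = usage_frequencies(clonotypes, axis="family", chain="IGH", segment="V")
print(table.wide()["IGHV3"].groupby(level="subset").mean().round(1))

res = [r for r in compare_usage(table, subsets=("preB", "naive"))
       if r.key == "IGHV3"][0]
print(f"IGHV3 pre-B vs naive: effect {res.effect:+.1f} points, "
      f"adjusted p = {res.adjusted_p:.2e}")
```

prints

```
100574 reads, 40000 true clonotypes
40799 unique rearrangements after dedup
subset
immature        55.1
naive           41.3
preB            55.1
transitional    47.6
Name: IGHV3, dtype: float64
IGHV3 pre-B vs naive: effect -13.8 points, adjusted p = 5.42e-05
```

The simulator planted a 14-point IGHV3 family decrease between pre-B
and naive cells; the pipeline recovers −13.8 points from the noisy,
PCR-duplicated reads and flags it significant after multiplicity
adjustment. A command-line interface wraps the same steps
(`bcelldev sim|clean|props|usage|mv|all`); `bcelldev all --config
run.yaml` runs every stage and writes a checksummed run manifest.

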