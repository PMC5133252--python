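# Methods

## Data model

The pipeline starts at the annotated-rearrangement layer: one row per
sequenced read carrying germline V/(D)/J gene calls, the junction, a
productivity flag, and donor/subset labels. Germline assignment itself
(IMGT/HighV-QUEST or equivalent) is treated as an upstream black box;
the simulator supplies ground-truth annotation in the same schema. Gene
names follow IMGT conventions; the family is the digit group after the
segment letter (IGHV3-30 → family 3) and allele suffixes (`*01`) are
stripped on parse. Internally the CDR3 excludes the conserved anchors
C104 and W/F118; IMGT-style `junction` columns, which include them, are
trimmed on load (AIRR `cdr3`/`cdr3_aa` columns are taken as-is). Tables
written by the package use the anchor-free AIRR `cdr3` columns, making
write→read round trips exact.

## Cleanup and PCR-duplicate collapse

Two filter stages mirror the two uses of the data. The *gene stage*
(for usage analyses) only requires parseable gene calls and a non-empty
CDR3, keeping unproductive rearrangements, which are informative about
recombination. The *CDR3 stage* (for peptide analyses) additionally
requires productivity, a translatable standard-alphabet CDR3, and a
CDR3 length inside the chain window — 1–35 aa (heavy) or 1–20 aa
(light), inclusive on both ends. Every removed record carries exactly
one reason code, and kept + removed always partitions the input.

Duplicate collapse assumes antigen-naive populations: reads with the
same (or nearly the same) CDR3 are PCR copies of one gene
rearrangement. Unique CDR3 strings are single-linkage clustered under
unit-cost Levenshtein distance (computed by edlib) within each donor ×
subset × chain × V gene × J gene group; a pair is compared only when
the length difference does not exceed the threshold, which is exact
pruning because length difference lower-bounds edit distance. The
default threshold of 1 nt absorbs single sequencing errors; threshold 0
reproduces exact-CDR3 grouping. Keying on the V and J calls encodes the
view that a "gene rearrangement" shares its gene segments, and bounds
the quadratic clustering cost; the key is configurable
(`key="donor_subset_chain"` clusters on CDR3 alone). Each cluster emits
one clonotype represented by its modal member — the most frequent
sequence, ties broken lexicographically (a per-position consensus was
considered and rejected: it can synthesize a sequence observed in no
read). Conservation (member counts sum to the input), idempotence, and
monotonicity in the threshold are enforced by tests.

With the default error rates, a read carrying two or more errors in its
CDR3 sits at edit distance 2 from its clonotype and founds a spurious
singleton at threshold 1; at 0.2% substitution error this inflates the
clonotype count by ~2%, which is the accuracy envelope the stress tests
assert.

## CDR3 descriptors

All scales ship as versioned CSV files covering the 20 standard
residues. Mean-type descriptors (GRAVY on the Kyte–Doolittle scale,
Boman index, Kidera factors) are arithmetic means of per-residue
values, so a homopolymer's value equals its table entry — a property
the test suite asserts for every residue. The Kidera table's ten
columns are normalized (mean ≈ 0, SD ≈ 1 over the residues) to within
0.05, which is asserted rather than assumed. Molecular weight uses
average residue masses plus one water (18.01524 Da). The isoelectric
point solves net charge = 0 with Henderson–Hasselbalch terms for the
termini and the C/D/E/H/K/R/Y side chains using the EMBOSS pKa set (the
Lehninger/IPC sets can be swapped in via a custom `ScaleTables`); the
charge is strictly decreasing in pH so bisection on [0, 14], run to an
interval of 1e-7, is exact for practical purposes and is verified
against a 1e-4-step grid scan to within 0.001 pH. The aliphatic index
is Ikai's weighted mole-percent formula; class counts use the common
nine-class partition (tiny/small/aliphatic/aromatic/nonpolar/polar/
charged/basic/acidic). Sequences with ambiguous residues (X/B/Z) are
rejected from the property stage with a logged reason rather than
scored approximately. Properties are computed on the anchor-free CDR3;
including the anchors would add a constant C and W/F contribution to
every sequence and shift, but not reorder, subset comparisons.

## Usage statistics

Frequencies are always percentages of *unique clonotypes* per donor ×
subset (never raw reads, which would re-import the PCR bias the
collapse removed), at gene, family, or family-combination (VDJ / VJ)
resolution; absent keys are explicit zeros so every donor × subset cell
sums to 100. Subset comparisons treat per-donor frequencies as
replicates: per-key pairwise contrasts (t tests, paired when both
subsets cover the same donors — bone-marrow and blood subsets come from
the same donors in this design) adjusted by Holm–Šidák across all key ×
pair hypotheses (Benjamini–Hochberg available), plus rank-based paired
Wilcoxon / Mann–Whitney alternatives and a global two-way
(subset × key) ANOVA. Identical groups yield p = 1 by convention rather
than NaN. Donor × subset cells with no clonotypes are dropped, not
imputed.

The mixed model for CDR3 properties is a Gaussian random-intercept
model, y ~ subset + (1|donor), fitted by maximum likelihood (not REML,
because the LRT compares fixed-effect structures) via statsmodels
MixedLM; the LRT statistic 2Δℓ is referred to χ² with (#subsets − 1)
degrees of freedom. An exact closed-form implementation of the marginal
log-likelihood (Woodbury identity per donor block) doubles as the
convergence oracle: tests verify the ML solution against direct
numerical optimization of the 4-parameter likelihood to 1e-3 in
log-likelihood, and 200-replicate null simulations bound the empirical
type-I error within [0.02, 0.09] at α = 0.05.

## Multivariate analyses

Features (family frequencies, or clonotype-level property means) are
first averaged per donor × subset. PCA is SVD-based with centering on
and unit-scaling off by default (both exposed), deterministic up to
sign, which is fixed by making each component's largest-magnitude
loading positive; scores reconstruct the centered matrix exactly.
Subset separation is summarized by the between-subset share of
dispersion of the first two score dimensions (between-centroid sum of
squares over total sum of squares) — a package construct chosen because
it is rotation-invariant and bounded in [0, 1], not a quantity with an
external definition. Its null distribution comes from permuting subset
labels across sequences within each donor (preserving subset sizes and
donor effects; a global shuffle is available by flag), re-running the
entire donor-means → PCA pipeline per permutation, and using the
add-one estimator p = (1 + #{perm ≥ obs}) / (n_perm + 1), which is
never zero and exactly reproducible under a seed.

Hierarchical clustering uses the Minkowski distance with power 4 —
emphasizing the largest single-coordinate difference between repertoire
profiles — with complete linkage by default (single/average/ward
configurable; the linkage choice is a genuine free parameter here).
Dendrograms serialize to Newick with branch lengths derived from merge
heights.

## The simulator

`simulate_repertoire` emulates the generative structure the analyses
assume, not any real locus. Per clonotype: V/(D)/J are drawn by family
frequency then within-family gene weight from a synthetic germline
bundle (named after real human genes, with conserved V-end Cys and
J-anchor Trp/Phe codons so CDR3 extraction is well defined; sequences
are deterministic from a seed and checked into the repo). A target CDR3
length is drawn from the subset's Normal(mean, sd); the CDR3 is
assembled from the trimmed germline V tail, Poisson N-insertions, the
geometrically trimmed D, more N nucleotides, and the trimmed J head,
then adjusted to the target length from the middle outward so the
germline ends are preserved. Two-thirds of clonotypes are forced
in-frame and stop-free (stop codons resampled); the rest are
frame-shifted and unproductive. Each clonotype yields
1 + Poisson(pcr_copies_mean − 1) reads with independent per-base
substitution (default 0.2%, a 454-like order of magnitude) and indel
(default 0.05%) errors; homopolymer-biased indels are not modelled.
Gene calls are never perturbed by error, reflecting the observation
that sequencing error rarely changes the germline assignment.

Defaults are the analysis conditions: 5 donors with ages evenly spread
over 24–86 years, 5000 clonotypes per subset per donor, seed-controlled
throughout (identical config + seed ⇒ byte-identical output). Baseline
family frequencies (e.g. IGHV3 = 0.55 in bone marrow) are synthetic
constructs; the *planted subset differences* are the signal, each set
strictly above the bound the recovery analyses must clear: IGHV3
−14 points (pre-B → naive), IGHJ6 +9.5 (transitional), IGHD2 −7
(peripheral subsets), IGHD3 +5.5 (transitional), IGLV2 +12 and IGLJ1
+3.5 (immature → peripheral, the IGLJ1 gain taken from IGLJ3), with
kappa families flat across subsets. When a family is shifted the
complement is redistributed proportionally over the unshifted families
(IGHD3 is pinned at baseline in naive so the transitional excess is
exactly as planted). Within-family gene weights are uniform except for
a few genes given peripheral up/down-weights (IGHV3-15/-30/-33 down,
IGHV3-9, IGHV1-18/-69 up; IGLV2-14/-23 up; IGKV3-11 up, IGKV3-20/
IGKV4-1 down); these gene-level garnishes do not alter family totals.
Heavy-chain CDR3 length means shrink 16.0 → 15.0 aa from pre-B to
naive (SD 3), and `age_length_coupling` (default 0.25 aa per decade
past 50, scaled by developmental stage) attenuates that decline in
older donors. Light chains cover immature/transitional/naive only,
since pre-B cells have not completed light-chain rearrangement.

`default_profiles(variant=...)` exposes three planting schemes:
`"full"` (all shifts; the default), `"transitional_only"` (only the
transitional-specific shifts against a shared baseline), and `"null"`
(no shifts). The qualitative dendrogram check — transitional donor-rows
isolating as the outgroup under power-4 clustering — uses the
`transitional_only`/`null` pair: under the full defaults the planted
14-point naive IGHV3 shift is the largest single coordinate and the
power-4 metric makes *naive* the outgroup instead. This is a known
difference between the synthetic geometry and real repertoires, where
the transitional population's distinctiveness exceeds the
bone-marrow-to-naive drift.

### What passing tests do and do not show

The simulator plants family shifts as independent multinomial draws per
clonotype; real repertoires have correlated V–D–J choices, allelic and
primer biases, clonal structure, and gene-specific CDR3 composition,
none of which are modelled. Recovery of the planted deltas therefore
demonstrates that the pipeline measures what it claims (frequencies
over correctly deduplicated clonotypes, calibrated tests), not that
real data would show effects of these magnitudes. Absolute sequence
counts and dataset-specific quantities (e.g. a PC1 variance share) are
deliberately out of scope.

## Problem sizes and numerics

Headline recoveries run at the default scale (5 donors × 5000
clonotypes per subset per donor; ~250k heavy-chain reads, ~100k
clonotypes), which gives per-donor family-frequency sampling noise of
well under one percentage point; calibration suites use 200 simulated
replicates with smaller per-replicate sizes (6–8 donors, 10–25
observations per cell) chosen so the null statistics are comfortably
estimated. The IGHD3 recovery target subtracts a 0.5-point sampling
tolerance from the measured excess. Ties in modal-sequence selection
break lexicographically; permutation p-values use the add-one
convention; all stochastic tests fix their seeds.
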