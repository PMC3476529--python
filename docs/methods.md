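# Methods

## Problem and approach

`xcmap` asks whether cell populations sorted from different tissues — and
different species — are the "same" cell type at the transcriptome level.
The motivating system is dendritic-cell (DC) biology: human blood and skin
contain several DC and monocyte subsets (CD141-high, CD1c+, CD14+, CD16+
monocytes, pDC), mouse nonlymphoid organs contain CD103+ and CD11b+ DCs and
spleen contains CD8+ and CD4+ DCs, and the question is which human subset is
the functional homolog of which mouse subset.  The package implements the
computational side of that comparison:

1. remove *tissue-specific* genes so signatures reflect subset identity, not
   anatomical origin;
2. derive rank-based up/down *gene signatures* per subset, and pooled
   *lineage* signatures spanning tissues;
3. score signatures against reference expression profiles with a
   directional KS *connectivity* statistic, scaled to [-1, 1], with
   permutation significance;
4. translate human signatures into mouse gene space through an ortholog
   table and repeat the scoring against mouse subsets;
5. cluster subset-mean profiles hierarchically (correlation distance) to
   display the same structure as a dendrogram.

## Ranking statistic and signatures

Per gene, target-vs-rest separation is the signal-to-noise ratio
`SNR = (mu_t - mu_r) / (sd_t' + sd_r')` with each group's standard deviation
floored at `max(0.2*|mu|, 0.2)`.  The floor is the GSEA-family convention:
without it, near-constant genes dominate the ranking.  Standard deviations
use the population form (`ddof=0`) so that duplicating a sample set — the
degenerate case of pooling a subset with itself — leaves the statistic, and
hence the signature, exactly unchanged.  The up list is the top `size` genes
by SNR, the down list the bottom `size` (default 150 + 150, a mid-range
connectivity-query size; exposed as a flag).  Ties are broken by gene id so
derivation is fully deterministic and invariant to sample column order.
Because the floor depends on |mean|, a global intensity shift perturbs the
ranking slightly near the tag-list boundaries; the tests pin ≥85% tag
overlap under a 1.5 log2-unit shift (measured ~95%).

## Tissue filter

Tissue-specific genes are found within *matched* subsets — subsets with ≥2
samples in both tissues.  The default method fits, per gene, one ordinary
least-squares model with a tissue indicator and subset dummies over all
matched samples, then applies a single Benjamini–Hochberg pass at FDR 0.05
to the tissue-coefficient p-values.  Pooling matched subsets in one blocked
model is what makes the per-gene test usable at microarray-scale
replication: with only 6 blood and 4 skin donors, an independent Welch test
inside each subset followed by per-subset BH (available as
`method="per_subset_union"`) has so little power that BH collapses —
simulation at the default design shows ~5% recovery of planted tissue genes
for the per-subset union versus ~97% for the blocked model, at comparable
empirical FDR.  The blocked model assumes a shared tissue effect and
homoscedastic noise across matched subsets, which is exactly the generative
model of the synthetic cohort and a reasonable approximation for normalized
microarray data.

The filter is applied before signature derivation (filter-first).  Donor
offsets are not modelled in the filter; because human blood and skin donors
are disjoint, a chance imbalance in donor offsets acts as a small global
tissue contrast and is the main source of false positives (empirical FDP
~5% at nominal 5%).

## Connectivity score

For a tag set of size `t` at ascending positions `V(1..t)` in a ranked list
of `n` genes:

    a = max_j( j/t - V(j)/n ),  b = max_j( V(j)/n - (j-1)/t )
    ks = a  if a > b  else  -b

The raw connectivity of a signature is `ks(up) - ks(down)` if the two KS
statistics have opposite signs, else 0 (the classic connectivity-map
same-sign rule: when both tag lists drift the same way there is no coherent
connection).  Raw scores from one run are scaled jointly — positives by the
maximum positive, negatives by |minimum negative| — giving dimensionless
scores in [-1, 1] comparable within a panel.

Reference profiles are ranked by expression *centered on the per-gene panel
mean*.  Ranking raw intensities would order genes by their baselines, which
carry no subset information; centering makes the ranking a differential one,
the standard connectivity-map practice.  The `rank_profile` primitive itself
ranks whatever values it is given (descending, ties by gene id).

## Permutation significance

Significance of a score against one ranked profile comes from `B = 1000`
random signatures with matched tag-list sizes drawn from the profile's
universe, with the add-one estimator `p = (1 + #{|null| >= |obs|}) / (B+1)`
(two-sided; minimum attainable p = 1/(B+1)).  The permutation statistic is
the *directional* difference `ks(up) - ks(down)` **without** the same-sign
zero rule.  This is deliberate: the zero rule maps about half of all random
signatures to exactly 0, so any p-value defined on the zero-ruled score has
an atom of mass ~1/2 at p = 1 and cannot be uniform under the null.  The
directional statistic is continuous and exchangeable with its permutation
null, so the reported p-values are calibrated — verified by a KS
goodness-of-fit test against U(0,1) on a no-signal cohort.  A profile can
therefore show a reported score of 0 (incoherent direction) together with a
small p; both pieces of information are kept.

Subset-level summaries are the mean scaled score and the median of the
per-sample p-values (robust; the per-sample p's are what the test actually
produces).

## Orthology

The default mapping policy keeps only reciprocally unique (1:1) ortholog
pairs; `expand_all` includes every ortholog.  A target gene landing in both
tag lists after mapping is removed from both.  If either mapped list retains
less than 20% of its source genes the signature is rejected as no longer
representative.  Retention fractions are reported per list.

## Clustering

Distances are `1 - Pearson r` between subset-mean profiles over all retained
genes; linkage is average (complete available).  Pearson correlation is
location/scale-free per profile, so per-donor global offsets cancel.  Leaves
are canonicalized to lexicographic order before linkage, making the
dendrogram invariant to input order; Newick export carries branch lengths
derived from merge heights.

## Synthetic cohort generator

The generator is the package's test bed and emulates the study design it is
modelled on:

* **Human**: CD141_DC, CD1c_DC, CD14_DC in blood and skin; CD16_monocyte and
  pDC in blood only; six blood donors and four skin donors, each donor
  contributing one sample per subset in its tissue (30 blood + 12 skin
  samples).
* **Mouse**: CD103_DC and CD11b_DC in lung and liver, CD8_DC and CD4_DC in
  spleen, monocytes in blood; four experimental sets, each contributing one
  replicate per subset-tissue (28 samples).
* **Lineages**: CD141_DC↔{CD103_DC, CD8_DC} (`cd141_like`),
  CD1c_DC↔CD4_DC (`cd1c_like`), {CD14_DC, CD16_monocyte}↔monocyte
  (`monocyte_like`), pDC human-only (`pdc_like`), CD11b_DC unassigned
  (deliberately heterogeneous).  Marker genes of shared lineages correspond
  through 1:1 orthologs.

Expression is additive Gaussian on the log2 scale: per-gene baseline
Uniform(4, 12) (typical normalized microarray intensities), lineage effect
2.0 on 80 marker genes per lineage, tissue effect 1.0 on 100 genes per
tissue, per-donor scalar offset N(0, 0.1), i.i.d. noise N(0, 0.5), 2000
genes, 90% of genes with a 1:1 ortholog (optional one-to-many injection,
default off).  The tissue effect equals twice the noise standard deviation —
a moderate batch-like effect; the donor offset is small because global
shifts are largely removed by normalization in real data.  Marker sets are
disjoint across lineages and from tissue genes, and (to keep cross-species
recovery interpretable) tissue genes are also drawn outside every species'
marker set.

What the generator does **not** emulate: probe-level artifacts, mean–variance
coupling of real microarrays, correlated gene modules beyond the planted
blocks, many-to-many ortholog families (unless injected), and lineage
effects of heterogeneous magnitude.  Passing tests therefore demonstrate
correctness and calibration of the procedures under a clean additive model,
not performance guarantees on real arrays.

## Determinism and numerics

Every stochastic step takes an explicit seed.  Pipeline runs fork one seed
per stage via `SeedSequence([seed, crc32(stage)])`, so inserting a stage
does not shift another stage's draws.  Output floats are formatted with
`%.10g`, giving byte-identical files on rerun.  Degenerate inputs fail fast:
duplicate ids, missing annotations, non-finite values, empty tag sets, tag
sets outside the universe, zero-variance profiles, asymmetric distance
matrices, sub-2-replicate designs.

## Problem sizes in the test suite

The suite exercises the defaults end to end: 2000-gene cohorts, 10 seeds
for the recovery/structure properties, exhaustive KS oracle enumeration up
to n = 12 plus 1000 random instances up to n = 50, 200 permutation tests at
B = 1000 for calibration, and B = 100 permutations in the byte-determinism
runs — the full suite and the acceptance script each finish in well under a
minute on one CPU core.

## Known limitations

* Two tissues per species in the filter; multi-tissue designs would need a
  multi-way model.
* The blocked filter's equal-variance assumption; a moderated (empirical
  Bayes) variance model is out of scope.
* Unweighted KS running sum (no exponent weighting, no leading-edge
  extraction, no cross-signature FDR).
* Subset-level p aggregation by median is a reporting convention, not a
  combined test.
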