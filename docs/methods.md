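# Methods

This note documents the statistical model behind `btukit`, the design
choices that were genuinely open, the synthetic data model and what it does
and does not emulate, and the numerical conventions.

## Input model and filtering

A dataset is an ASV count table (samples × ASVs), the ASV marker sequences,
a taxonomy table (phylum…genus, ranks may be unassigned), a sample → host
species map, and a rooted host phylogeny whose tips cover all species.
Filtering is **taxa first, then samples**: ASVs unassigned at phylum level
or matching Chloroplast/Mitochondria/Archaea (case-insensitive prefix, since
database spellings vary) are removed, and only then are samples with fewer
than `min_sample_reads` (default 1000, strict inequality) dropped — so a
borderline library whose reads are mostly organellar is discarded.  The
order matters for borderline libraries and is fixed explicitly; the package
makes no claim that any particular upstream workflow used the same order.

## BTU definition

*Reference-based*: one BTU per distinct genus string; genus-unassigned ASVs
are excluded and counted.

*Reference-free*: pairwise distances between aligned markers are corrected
with the Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3) (p = mismatch
fraction over gap-free site pairs; p ≥ 3/4 saturates to +∞, treated as
"never merge"), and a complete-linkage dendrogram is cut at height
h = 1 − similarity (0.03 / 0.05).  Complete linkage guarantees that every
within-BTU pair is within h, and the package re-asserts this on every
produced partition.  Cutting the same dendrogram at both heights makes the
95% partition a coarsening of the 97% partition by construction.  The cut is
applied on the *corrected* distance scale by default, even though corrected
distance ≠ 1 − identity; `pairwise_distances(..., correction="raw")`
switches to uncorrected mismatch fractions.

Alignment: sequences of equal length are taken as positionally homologous
(the indel-free, same-locus amplicon assumption) and returned unchanged.
When lengths differ, a center-star multiple alignment is built: the center
minimizes summed 4-mer city-block distance, every other sequence is globally
aligned to it (match +1, mismatch −1, gap −2) and gap patterns are merged.
A scoring aligner is deliberately *not* run across equal-length inputs:
between deeply divergent (saturated) groups it chases chance matches and
introduces spurious gaps that distort within-group distances.  Center-star
is a reasonable stand-in for profile aligners on near-identical-length
amplicons; it is not suitable for sequences with large indels.

BTU inclusion filters: at least `min_btu_reads` (5000) reads **and**
`min_btu_asvs` (10) ASVs, both inclusive, applied per partition; retained
read fractions are logged.

## Host-species specificity (PERMANOVA)

Counts are converted to proportions of the **whole-sample** library before
any BTU subsetting (a BTU slice of a sample sums to the BTU's share of the
library, not to 1); within-BTU renormalization is available as a sensitivity
flag only.  Per BTU, the hosting samples (≥ 1 read over the BTU's ASVs)
define the analysis set; BTUs with < 3 hosting samples or < 2 hosting
species are flagged untestable and logged, never silently dropped.

Dissimilarities: Bray–Curtis BC = 1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ) and the classic
set-form binary Jaccard J = 1 − |supp∩|/|supp∪| (not the 2B/(1+B) transform
of binary Bray–Curtis; the two are monotone transforms of each other, so
permutation ranks are nearly unaffected, but values differ).

The PERMANOVA pseudo-F uses the standard distance formulation: with
SS_total = Σ_{i<j} d²ᵢⱼ/n and SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ/n_g,

    F = [SS_model/(k−1)] / [(SS_total−SS_model)/(n−k)],  R² = SS_model/SS_total,

algebraically identical to the trace form tr(HGH)/tr(G) on the
Gower-centered matrix G = −½CD²C.  Non-Euclidean matrices are used as-is
(no Lingoes/Cailliez correction), matching standard practice.  Significance
comes from unrestricted random relabeling of samples (the permutation is
*not* stratified; blocks enter only in the PACo null below), with the
add-one estimator p = (1 + #{F* ≥ F})/(1 + n_perm), default n_perm = 10 000.
R²adj = 1 − (1−R²)(n−1)/(n−k) is the one-factor Ezekiel form; it may be
negative.  Permutation streams are derived from (seed, method, BTU) only, so
Bray–Curtis and Jaccard runs of the same BTU share permutations and their
effect-size concordance is not inflated by permutation noise.

The high-specificity subset test draws `n_perm` random ASV subsets of the
same size as the target (uniformly, without replacement, from all retained
ASVs), rebuilds the dissimilarity and recomputes R²adj for each draw; note
that when the target is a large fraction of the community the null draws
overlap it heavily and the test is intentionally weak — it is informative in
the realistic regime where high-specificity ASVs are a small minority.

## Co-divergence (PACo)

Both PACo modes use **symmetric Procrustes**: each configuration is
column-centered and scaled to unit total sum of squares; the optimal
rotation comes from the SVD of XᵀY; m² = 1 − (Σ singular values)² and
r = √(1 − m²).  Column counts need not match (zero-padding leaves singular
values unchanged, so none is applied).  Symmetric scaling makes r
order-symmetric; the original PACo's asymmetric scaling is a known variant,
and m² is used consistently for significance either way.

*Host side*: species cophenetic distances are lifted to samples with
d(sᵢ,sⱼ) = coph(species(sᵢ), species(sⱼ)) — zero within species, so
same-species samples are coincident points in the host embedding.  This is
the natural sample-level lift of a species-level distance.

*P_COMP*: response = PCoA of the BTU's sample dissimilarities, explanatory =
PCoA of the lifted host matrix, identity row pairing.

*P_PHYLO*: response rows = ASV-side PCoA coordinates and explanatory rows =
host-side coordinates of the occurrence's sample, one row per (ASV, sample)
occurrence with count ≥ 1 (an ASV × species granularity is a coarser
alternative; the sample granularity is the default because it weights
occurrences by how often they are observed).  Genetic distances within a BTU
use JC69 or K80 closed forms; the model is chosen by AICc of two-sequence
likelihoods summed over pairs with per-pair parameters.  AIC-family criteria
retain the richer model on a minority (≈ 16% per independent comparison) of
null realizations — this is a property of the criterion, not a defect of the
implementation.  Saturated pairs return +∞; a matrix containing any sentinel
makes the BTU fall back to raw p-distances, flagged in the logs.  TN93/F81
and full model scans are out of scope.

*Null model*: species identities are reshuffled across intact blocks of
same-species samples; the host-side configuration is rebuilt and m²
recomputed each round; p = (1 + #{m²* ≤ m²})/(1 + n_perm) (small m² =
congruent).  With one sample per species this reduces to an ordinary label
permutation.  Implementation detail: for balanced designs the permuted host
matrix is a row/column permutation of the observed one, so the null reuses
the observed embedding's per-species coordinates (exact, since m² is
invariant to rotation/reflection); for unbalanced designs this is exact
whenever the embedding reproduces the cophenetic distances (ultrametric
distances are Euclidean-embeddable, so in practice it is), and
`exact_perm=True` forces a full re-embedding per round.  Uniform random
permutations occasionally draw the identity, so under perfect congruence the
p-value sits slightly above the add-one floor 1/(n_perm+1) — the standard
behavior of sampled permutation tests.

*Degenerate BTUs*: a BTU whose ASVs are genetically identical has a
zero-variance ASV-side configuration; P_PHYLO is then untestable and logged.
Similarly, near-complete occurrence matrices (every ASV in every sample)
carry almost no information for P_PHYLO and the test becomes conservative —
real and realistic synthetic BTUs are sparse, where calibration is exact.

*Mantel*: Pearson correlation of condensed triangles, BTU profiles averaged
per species against cophenetic distances, one-sided p by jointly permuting
rows and columns of one matrix.  It is reported as a cross-check only.

## FDR and reporting

BH step-up FDR is applied separately per (binning method × distance ×
statistic) family; P_PHYLO does not depend on the community distance, so it
is computed once per BTU and joined to both distance sections, with its own
family.  Effect-size concordance across BTUs (R²adj vs P_COMP vs P_PHYLO;
Bray–Curtis vs Jaccard) uses tie-corrected Kendall τ-b.  The accounting
table assigns every retained ASV and read to exactly one of
untested / nonsignificant / significant / high-effect (significant with
effect > 0.2), and the pipeline asserts read/ASV conservation.

## Synthetic community model

The generator emulates the *shape* of a processed cross-species survey —
many host species, a few fecal samples each, libraries of a few thousand
reads — with planted per-BTU regimes:

- **Host tree**: pure-birth (Yule, rate 1), started at the first split (no
  root edge), rescaled to unit height; ultrametric by construction.
- **Sequences**: per BTU, a guide tree (Yule for null/specific; a mirror of
  the host tree for codiverging BTUs, which therefore carry exactly one ASV
  per species) rescaled to unit height; sites evolve independently under
  JC69 from an independent uniform-random root at `substitution_rate`
  expected substitutions/site root-to-tip (default 0.005, small enough that
  planted BTUs stay within the 97% similarity floor while BTU roots are
  mutually saturated — so reference-free clustering can recover the planted
  partition exactly).
- **Affinities** (ASV × species occurrence propensities): uniform for null;
  Dirichlet(α·1) for specific (α = `specificity_concentration`, default 0.1;
  smaller α concentrates an ASV on fewer, phylogenetically random species);
  for codiverging, a phylogenetic decay kernel exp(−coph(i,j)/(τ·H))
  (τ = `phylo_kernel_scale` = 0.2 tree heights) blended with a uniform floor
  ε = `codivergence_leakage` (default 0).  The kernel is what makes expected
  *composition* track host phylogeny — a uniform leakage around a diagonal
  affinity would make all between-species expected dissimilarities equal and
  hence carry no phylogenetic gradient at all, leaving the permutation test
  without power by symmetry.  ε is the continuous strength knob: ε = 1 is
  the null.
- **Abundances**: each ASV carries a lognormal base abundance (σ = 1.5,
  shared across species — so the null contract "identical expected relative
  abundance in every species" is preserved while occupancy varies across
  ASVs, as in real communities).  Per species, expected composition gives
  each BTU equal mass and splits it within the BTU proportionally to
  base × affinity.  Counts are multinomial draws per sample with negative
  binomial library sizes (mean 6000, dispersion 10).
- **Taxonomy**: each planted BTU gets a unique synthetic genus, so
  reference-based binning recovers the planted partition exactly; all ranks
  are assigned, so the taxon filter is the identity on synthetic data.

One RNG stream per dataset is split by stable keys in a documented order
(host tree; per BTU: guide tree, sequences, affinities, base abundances;
library sizes; per-sample counts).  Identical seeds give bit-identical
outputs within this implementation; across implementations only the
contract, not the bits, is portable.

Not emulated: read-level error, chimeras, PCR/primer bias, indels,
compositional overdispersion beyond the multinomial, unassigned taxonomy,
within-species ecological structure.  Passing tests therefore demonstrate
the correctness and calibration of the *statistics* under a controlled
community model, not robustness to upstream artifacts of real surveys.

## Test and acceptance problem sizes

Simulation sizes in the test suite are desk-scale choices: type-I
calibration uses 500 single-BTU replicate datasets (8 species × 3 samples,
30 ASVs, sparse occupancy, n_perm = 199) checked against the binomial 95%
band around α = 0.05; power/recovery uses 40 datasets at the default desk
configuration (20 species × 5 samples, 4 BTUs per regime × 25 ASVs,
n_perm = 299) with FDR applied within each dataset; the strength-
monotonicity check spans five Dirichlet concentrations (10…0.1) × 6 matched
seeds; the clustering guarantee is asserted on 100 random matrices and all
synthetic runs; and the paper-shape smoke run (20 species / 100 samples /
~1000 ASVs, all three binning methods, both distances, n_perm = 999)
completes in a few minutes on one CPU.  `scripts/acceptance.py` uses the
default desk configuration with n_perm = 999 and a 10-dataset recovery
study.

## Known limitations

- Center-star alignment is only adequate for near-equal-length amplicons;
  no profile or structure-aware alignment.
- The substitution-model scan is reduced to {JC69, K80}; distances, not
  tree likelihoods.
- P_PHYLO is conservative for BTUs with near-complete occurrence matrices
  (little incidence information).
- Monophyly of BTUs is assumed from the construction (genus identity or a
  similarity floor), not tested.
- The PERMANOVA permutation is unrestricted; with strong within-species
  correlation *and* unbalanced designs a restricted scheme could differ.
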