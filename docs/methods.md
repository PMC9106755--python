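# Methods

This note records the models, estimators, numerical conventions and design
choices behind `musadiv`, and what the synthetic-data tests do and do not
establish.

## Data model

Fingerprints are genotype × locus matrices over {0, 1, missing}; a locus is
identified by (primer, marker system, band label). Band labels stay free
text — published tables mix "0.75 Kb" and "750 bp", and nothing downstream
needs the size. All tabular I/O is CSV (UTF-8, `NA` for missing); writers
use fixed column order and `%.4f` floats so pipeline bundles are
byte-reproducible. Missing cells are excluded locus-wise (frequencies) or
pairwise (distances, similarities); a pair of genotypes with no jointly
scored locus is an error, not a silent zero.

## Dominant-marker estimators

Dominant bands hide heterozygotes, so allele frequencies come from the
band-absence frequency: q = (1 − p̄)^(1/m) under random union of m allele
copies. The default scheme uses m = 2 (the classical dominant-diploid
estimator); a ploidy-aware scheme accepts m ∈ {2, 3, 4} for panels treated
at a uniform ploidy. Per-locus diversity uses the two-allele formulas
Ne = 1/(p² + q²), I = −(p ln p + q ln q) (0·ln 0 ≡ 0), He = 2pq, and the
unbiased uHe = 2N/(2N − 1)·He, where N counts scored genotypes at the
locus.

Per-primer summaries count amplicons as 1-cells: a locus is polymorphic iff
its scored cells contain both 0 and 1; percent polymorphism is the
polymorphic share of 1-cells. This counting convention was chosen because
it reproduces the internal arithmetic of published per-primer tables (one
fixed-present locus in a 20-genotype panel contributes exactly 20
monomorphic amplicons). Polymorphism uses the strict criterion (any
frequency in (0,1)), not the 95% rule — appropriate for a 20-genotype
panel where one allele copy is 2.5% of the sample.

PIC for a dominant band is 2p̄(1 − p̄) (ceiling 0.5; the De Riek
convention), with 1 − Σpᵢ² available as an option. Resolving power is
RP = Σ_bands I_b, I_b = 1 − 2|0.5 − p̄| (Prevost & Wilkinson), and the
marker index is MI = mean-PIC × EMR with EMR = n_poly·(n_poly/n_total).
RP and MI appear in the literature under several non-equivalent formulas;
these defaults are stated here precisely because published tables alone
cannot disambiguate them.

## Similarity and trees

The shared-band coefficient S = 2a/(n₁ + n₂) (a = bands present in both
lanes) is the Dice/Nei–Li measure; joint absences carry no signal for
dominant markers and are ignored by construction. Jaccard and
simple-matching are available behind a flag but are not defaults.
Clustering runs on D = 1 − S: the similarity-vs-distance choice cannot be
recovered from legacy NTSYS analyses, and 1 − S keeps UPGMA heights
interpretable as (1 − similarity) levels for cutting.

UPGMA is implemented directly (not via scipy) so that tied minimal
distances resolve deterministically toward the lexicographically smallest
pair of sorted member-label tuples — trees are then invariant to input row
order, which scipy's index-based tie-breaking does not guarantee. scipy's
average linkage serves as an independent cross-check on merge heights in
the tests. Merge heights are full cophenetic distances; the Newick writer
halves them onto branches so leaf-to-leaf path lengths equal cophenetic
distances. Cutting at similarity s groups leaves connected strictly below
distance 1 − s (so s = 1 isolates every leaf, including duplicates).

## PCoA

Classical metric scaling: B = −½·J·D²·J, eigendecomposition via
`scipy.linalg.eigh`, coordinates = eigenvectors × √λ over eigenvalues above
1e-10 × λ_max. Dice distances are generally non-Euclidean, so negative
eigenvalues occur; they are reported but excluded from both coordinates and
the variance denominator (standard Gower treatment — cumulative percent
then ends at exactly 100 over the positive part). Axis signs are fixed by
making each axis's largest-magnitude loading positive. scikit-bio's PCoA is
the independent cross-check in tests, not the implementation.

## AMOVA

Squared distance between genotypes = band-mismatch count over jointly
scored loci (equals squared Euclidean distance on 0/1 vectors — the
standard choice for binary dominant data). One-level partition:
SS_total = (1/N)ΣΣ_{i<j} d², SS_within = Σ_p (1/n_p)Σ_{i<j∈p} d², with
df = k − 1 / N − k, n₀ = (N − Σn_p²/N)/(k − 1), σ²_w = MS_w,
σ²_a = (MS_a − MS_w)/n₀, Φ_ST = σ²_a/(σ²_a + σ²_w). Negative σ²_a is
reported as-is (unbiased-estimator convention), so Φ can be negative;
duplicating a non-constant population across two labels yields Φ = −0.5,
which is the estimator speaking, not a bug. The permutation test shuffles
whole genotypes across population labels and uses the add-one estimator
p = (1 + #{Φ_perm ≥ Φ})/(1 + n_perm), so the smallest reportable p is
1/(1 + n_perm) and p is bit-reproducible from the seed. A zero total
variance (all genotypes identical) reports Φ = 0 with a warning.

Per-population gene diversity is the locus mean of 1 − Σpᵢ² with the
n/(n − 1) small-sample factor (skipped and flagged for singleton
populations); heterozygosity for dominant input is the expected 2pq from
the within-population dominant estimate — an observed-heterozygote count is
not available from band data, so both quantities are model-based.

## Bayesian-clustering summaries

Evanno's ΔK = |L′(K+1) − L′(K)| / sd(K) over replicate LnP(D) means needs
≥ 2 replicates per K, contiguous K, and ≥ 4 K values; ΔK is undefined (NaN,
flagged) at boundary K and where the replicate sd is zero. ΔK depends only
on differences of means, hence is invariant to shifting all LnP(D) by a
constant. Membership calls use two thresholds: C (default 0.44) below
which the genotype is unassigned, and a purity threshold (default 0.7)
separating "pure" from "admixture" — the literature reports such splits
without defining the rule, so the second threshold is explicit and
configurable rather than implied.

## Volatilome

Kovats indices interpolate linearly between alkane anchors (exact 100n at
anchors; strictly increasing in retention time); retention times outside
the ladder span are errors, not extrapolations. RI matching uses a default
tolerance of 15 index units, a typical working width for semi-standard
non-polar columns. Class percentages are reported both unrounded (they sum
to exactly 100, which is what tests assert) and as half-up integers for
display — half-up reproduces the conventional "30 of 54 = 56%" reading;
note the nine rounded class percents of the reference table sum to 102, so
no rounded-sum invariant is claimed. The packaged reference table
(`fixtures/table10_volatiles.csv`: 54 compounds, 9 cultivars, 9 chemical
classes) was transcribed from a published cultivar table whose truncated
rows were resolved against its own per-class and per-cultivar subtotals;
the resolved matrix reproduces every subtotal exactly. One compound
(RT 26.476, a dimethoxy-methylbenzene) is listed there under both the
ester and ether sections and is kept as two records because the subtotals
require it. Cultivar clustering reuses the Dice + UPGMA machinery on the
presence matrix; a cultivar with no compounds makes similarity undefined
and is rejected.

## Synthetic data

The band generator is Balding–Nichols: p₀ ~ U(0.1, 0.9) per locus,
p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) per population (p_k = p₀ at F = 0;
F ≥ 0.95 rejected as degenerate), dominant expression
P(band) = 1 − (1 − p_k)^m for ploidy m. Defaults state the target panel:
20 genotypes in 4 subpopulations of 5, genome groups cycling through
AA/AB/AAA/AAB/ABB/AAAB, 34 primers (75 RAPD + 69 ISSR + 24 SSR loci),
F = 0.23. All draws flow from one `numpy` Generator per call, so runs are
replayable from a single seed.

What the generator does **not** emulate: linkage between loci, primer- or
size-dependent band-frequency spectra, genotyping error, or missingness
structure (missing cells are optional and uniform). A green downstream test
therefore establishes correctness of the estimators on exchangeable
Balding–Nichols panels, not agreement with any particular real panel whose
raw fingerprints are unpublished.

**Known, deliberate property — Φ_ST does not equal the allelic F.** AMOVA
on band mismatches measures phenotype-level differentiation (often written
Φ_PT). Under the dominant expression model the band frequency is a
nonlinear function of the allele frequency, which inflates
between-population variance relative to F: to first order the per-locus
ratio is 4(1 − p₀)/(2 − p₀) for diploids (≈ 1.27 averaged over
p₀ ~ U(0.1, 0.9), larger at higher ploidy). Measured on the default
recovery settings (4 × 25 genotypes, 300 loci, 10 seeds) simulated
F = 0.05/0.15/0.25 yields mean Φ_ST ≈ 0.08/0.21/0.34. Φ_ST is strictly
increasing in F (tested), but a recovery check expecting |Φ_ST − F| ≤ 0.05
fails for F ≥ 0.15, and the corresponding acceptance test is left failing
rather than recalibrated — the inflation is the model's mathematics, and
the SS partition itself is verified against an independent coordinate-based
oracle to 1e-8.

The LnP(D) generator builds a piecewise-linear mean curve with slope 120
per K below the true K and 8 above it (so the only curvature sits at the
true K) plus Normal(0, sd) replicate noise; at sd = 0.5 the ΔK argmax
recovers the true K in ≥ 90% of seeded runs. The volatile generator draws
retention times uniformly over the run window, computes experimental RIs
from a monotone ladder spanning the window, adds N(0, 5) scatter to form
reference RIs, and uses the reference table's class sizes (30 esters of 54)
as default composition with presence probability 1/3 per cultivar
(matching the reference table's mean occupancy of 18/54).

## Limitations

- No hierarchical (region/population/individual) AMOVA; one level only.
- SSRs are treated as dominant bands throughout; the codominant
  allele-size encoding used by admixture software is summarized
  (LnP(D), Q matrices) but never inferred here.
- No bootstrap support on dendrograms; topologies of small panels can be
  tie-sensitive even with deterministic tie-breaking.
- The dominant allele-frequency estimator assumes random union of gametes
  within populations; clonally propagated panels violate this, so He/uHe on
  real cultivar collections are descriptive indices, not HWE estimates.
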