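# Methods

## The analysis

The package asks whether genetic divergence between microbial isolates
increases with the geographic separation of their source sites
(isolation-by-distance), and whether genome-scale similarity thresholds
partition the isolates into species-level groups consistent with that
geography.

Inputs are (a) a site table with isolate names, sampling coordinates and
optional tectonic-plate labels, and (b) genetic similarity — either
precomputed pairwise matrices (in-silico DDH %, 16S identity %, ANI %) or
marker FASTA from which percent-identity matrices are computed. All
matrices are label-indexed, symmetric, and reconciled by name (never by
position); label-set mismatches are an error, not a silent intersection.

## Geographic distances

Coordinates are parsed from hemisphere-prefixed degree/decimal-minute
notation (decimal degrees = degrees + minutes/60; S/W negate; minutes must
be < 60). Distances are haversine great-circle distances on a sphere of
IUGG mean radius R = 6371.0088 km, with the haversine argument clamped to
[0, 1] so antipodal and rounding edge cases stay finite. A closed spherical
form was chosen over map-service or ellipsoidal geodesics for
reproducibility; the deviation from an ellipsoidal geodesic is below 0.5 %,
immaterial against matrices spanning thousands of km, though distances
reported by interactive map tools may differ slightly.

## Sequence identity

Percent identity uses global alignment with affine gaps (Gotoh
three-state dynamic programming). Defaults: match +1, mismatch −1, gap
open −2, gap extend −0.5 (a length-L gap costs open + L·extend), free end
gaps. Identity = 100 × matches / aligned columns, excluding terminal
overhang columns when end gaps are free — the "identity over the aligned
region" convention of the rRNA species-threshold literature. `N` never
counts as a match. Co-optimal alignments are resolved by a fixed traceback
preference (diagonal > up > left), and each pair is aligned in a canonical
orientation, so identity(a, b) == identity(b, a) exactly. The DP optimum is
verified against exhaustive enumeration of all alignments for short
sequences in the test suite. For equal-length ungapped sets (simulator
output) a Hamming mode (`method="hamming"`) scores 100·(1 − p) in O(L).

Similarities convert to distances elementwise as D = 100 − S. The
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is defined for observed
difference fractions p < 3/4; beyond that the model is saturated and an
error is raised rather than extrapolated.

## Mantel and Spearman tests

The Mantel statistic standardizes the d = n(n−1)/2 upper-triangle entries
of each matrix with their mean and *sample* (d−1) standard deviation, so
r_M = (1/(d−1)) Σ stand(x)·stand(y) is exactly the Pearson correlation of
the two vectorized triangles. The null distribution jointly permutes rows
and columns of one matrix. For n ≤ 7 all n! relabelings are enumerated and
the p-value is exact (the identity permutation keeps it positive); larger
n uses seeded Monte-Carlo with the add-one convention
p = (B_tail + 1)/(B + 1), which never reports 0 and is conservative under
the null (verified by a 500-replicate calibration test). Default
n_perm = 9999 and alternative = "greater" (the working hypothesis is a
positive distance–divergence correlation); a seed is mandatory whenever
Monte-Carlo runs. Statistics always run on distances: similarity inputs
are converted via 100 − S first and the report records the convention
(correlating similarity against distance would merely flip the sign).

The Spearman sympatry test rank-transforms (average ranks on ties) the d
genetic similarities and the d binary same-plate indicators and takes the
Pearson correlation of the rank vectors — the covariance of rank variables
over the product of their rank standard deviations — with the same joint
relabeling null. Plate labels are always user-supplied; sites on plate
boundaries get whatever label the analyst chooses, and nothing is inferred
from coordinates. An all-sympatric (or all-allopatric) set has zero rank
variance and is reported as degenerate rather than given a number.

## Species delimitation

Threshold clustering of a similarity matrix, inclusive comparisons (≥):

* **single linkage** (default): connected components of the graph with an
  edge where similarity ≥ threshold. This is the conventional reading of
  "the group shares ≥ X %", and on the packaged nine-strain DDH matrix it
  agrees with complete linkage at the 70 % species cut-off.
* **complete linkage**: groups fuse only if every cross pair meets the
  threshold; the merge with the highest minimum cross-similarity happens
  first, ties broken lexicographically.

Partitions are canonicalized (members sorted, groups sorted by first
member) and therefore invariant to input label order. Raising the
threshold only refines a partition (property-tested).

The pairwise decision table combines genomic DDH with 16S identity.
Defaults: ddh_species = 70, s16_species = 98.7 (revised cut-off),
s16_classic = 97. DDH dominates: ddh ≥ 70 with s16 ≥ 97 is
`same_species` (reported as `same_geovar_candidate` when the caller states
the two isolates come from distinct sampling sites — conspecifics separated
in space, i.e. geographic variants); ddh ≥ 70 with s16 < 97 is
`ambiguous` (conflicting markers); ddh < 70 is `distinct_species`, with an
`ambiguous_16s` flag when s16 ≥ 98.7 would have lumped the pair — the
situation of the Yellowstone isolate, whose 16S identity to the European
clade is 99.5 % while its DDH sits at 55–61 %. On the packaged data the
"maximum similarity from the Philippine/New Zealand pair to the other
strains" is exactly 21.6 (two cells of the table equal 21.6, so "less
than 21.6 %" in prose and the tabulated maximum coincide only at the
boundary; the package reports the table value).

## Synthetic data generator

The generator emulates the study regime — isolated geothermal "islands"
colonized stepwise, with divergence accumulating over the colonization
path — and is the package's source of known-truth datasets:

1. **Placement**: `uniform_sphere` draws lon ~ U(−180, 180], lat =
   arcsin(U(−1, 1)) (area-uniform); `clustered` draws k centers the same
   way and jitters members with a Gaussian of `cluster_spread_deg`
   (default 1°), recording cluster membership as the plate label.
2. **Colonization tree**: random root and arrival order; each new site
   attaches to the nearest already-colonized site (great-circle), ties to
   the lexicographically smaller name. A tree (rather than independent
   pairwise noise) guarantees the implied pairwise identities are
   realizable by an actual sequence set.
3. **Sequence evolution**: uniform-ACGT root; along an edge of length
   g km each site mutates independently with probability
   p(g) = (3/4)(1 − exp(−(4/3)·mu·g/1000)) to a uniform different base.
   Edge processes compose to Jukes–Cantor of the summed path, so expected
   corrected divergence is exactly mu × path_km/1000.

`mu` is parameterized as substitutions/site per 1000 km (default 0.005)
to keep human-scale magnitudes at the study's 10³–10⁴ km site spans.
Defaults: n_sites = 10, seq_length = 10 kb (20 kb in the recovery
harness). One root seed spawns per-stage child generators
(`numpy.random.SeedSequence`), so all outputs are bit-identical under a
fixed seed.

`recover_mu` inverts the generator: pairwise Hamming p-distances,
JC-corrected, regressed through the origin on tree-path distance; the
slope × 1000 estimates mu. Saturated pairs are excluded with a warning.
At the default harness size (10 sites, 20 kb) the estimate lands within a
few percent of truth; the acceptance harness requires 20 %, the bound
chosen from replicate spread at that problem size. With mu = 0 the
genetic matrix is constant and the Mantel stage raises its
degenerate-matrix error — the pipeline surfaces this rather than masking
it.

What the generator does *not* model: coalescent population structure,
migration after colonization, recombination, selection, rate variation
across sites, or indels. Passing tests therefore demonstrate correctness
of the machinery under a clean distance-driven divergence model, not that
real isolate collections satisfy that model.

## Pipeline and report

`run_pipeline` executes geodesy → identity matrices → Mantel (every
genetic matrix vs geography) → Spearman (vs sympatry, when plates exist) →
delimitation, and emits one JSON report with input hashes, seeds, all
statistics, partitions, and warnings. Strains without coordinates (in the
packaged data: SolV, V4, Kam1) are excluded from geographic analyses with
an explicit warning but retained for delimitation, mirroring the data
asymmetry (nine strains in the similarity tables, six with printed
coordinates). Degenerate matrices abort only the affected statistic. A
structural JSON schema ships with the package (`report.schema.json`) and
`validate_report` checks reports against it; reports contain no
timestamps, so identical configuration and seed reproduce byte-identical
output.

## Numerical choices and sizes

* Matrix symmetry/diagonal tolerance: 1e−9 absolute (inputs are
  hand-entered percentages).
* Matrix TSVs may be lower-triangular (mirrored on load), matching how
  pairwise similarity tables are printed; written cells use the shortest
  decimal representation that round-trips the float exactly.
* Permutation tail comparisons use a 1e−12 tolerance so exact ties count
  into the tail.
* Exhaustive-enumeration cut-over at n ≤ 7 (5040 relabelings).
* Test-suite problem sizes: alignment oracle at sequence lengths ≤ 8
  (1000 cases), null calibration at 500 replicates × 99 permutations,
  power at 100 replicates of 12 sites × 10 kb with 999 permutations —
  sizes at which the reference oracles are exact or the Monte-Carlo error
  is well below the asserted margins.

## Known limitations

* The Mantel permutation p treats distances as exchangeable under
  relabeling; spatial autocorrelation structure beyond the matrix itself
  is not modeled (no partial Mantel, no correlogram).
* Great-circle distances ignore terrain and dispersal corridors.
* The aligner is O(nm) per pair in pure Python: fine for markers up to a
  few kb, not for genome-scale input — genome relatedness is expected to
  arrive as precomputed DDH/ANI matrices.
* Complete-linkage clustering is greedy agglomerative with deterministic
  tie-breaking; for pathological tie structures other valid complete-link
  partitions exist.
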