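# Methods

`synrecruit` reimplements, as a tested pipeline, the analysis chain used to
profile coastal marine *Synechococcus*/*Cyanobium* communities from
whole-genome-recruitment (WGR) data and to characterise strain thermal
preferenda: two-pass alignment filtering with lowest-common-ancestor (LCA)
taxonomic assignment, clade-level community profiling with Bray-Curtis/UPGMA
station clustering and environmental comparison, and cardinal-temperature
growth-model fitting. Every stage can be exercised on synthetic data with
known ground truth; this note records the models, the defaults and why, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Reference taxonomy and LCA

The taxonomy is a rooted five-rank hierarchy, genus > subcluster > clade >
subclade > strain (e.g. *Synechococcus* > SC 5.1 > clade I > subclade Ia >
strain CC9311). Subclusters 5.2 and 5.3 typically carry no clade rank; their
strains attach directly under the subcluster, and the builder generally
attaches a strain to its nearest known ancestor when intermediate ranks are
missing. Outgroup reference genomes (non-picocyanobacterial aquatic
microbes, included upstream to absorb unspecific alignments) hang from a
distinguished sibling subtree directly under a universal root. Their own
internal taxonomy is irrelevant to the analysis — any candidate set touching
the outgroup resolves above the genus and the read is discarded — so
outgroup strains attach flat under that anchor.

`lowest_common_ancestor` takes the longest common prefix of the strains'
root paths. It is exercised in the test suite against an independent
brute-force oracle (intersection of explicit ancestor sets) together with
its algebraic laws: idempotence, permutation invariance, associativity, and
monotonicity under supersets.

## Two-pass read assignment

The pipeline consumes tabular alignment hits (BLAST outfmt-6 order with a
13th `qlen` column, or a separate read-length table); it does not run an
aligner. The upstream alignment parameters are treated as provenance; the
package re-applies only the parsing-stage filters, so results are
reproducible from any hit table at least as permissive.

* **Pass 1** (screen against the full database, best hit per read): a read
  survives when its best hit — maximal bit score, ties broken by minimal
  e-value then lexicographic genome id — has e-value < 1e-3, targets an
  in-group (picocyanobacterial) genome, and covers ≥ 90% of the read length.
* **Pass 2** (multi-target hits against in-group genomes only): candidate
  hits need identity ≥ 80%, coverage ≥ 90%, and bit score within 5% of the
  read's best bit score. The read is attributed to the LCA of the candidate
  strains; empty candidate sets, outgroup involvement, or an LCA above the
  genus leave the read unassigned (counted separately in the run log, which
  asserts read conservation: input = assigned + unassigned + missing).

Boundary policy: comparative filters are inclusive (≥ 80, ≥ 0.90,
≥ 0.95 × best) and the e-value bound strict (< 1e-3). The aligned-fraction
denominator is the full read length. "Score" in the 5% window means the bit
score, the comparison-stable final column of the tabular format. Alignment
lengths may exceed the read length by up to 10% (gap columns); anything
larger is rejected as malformed. These conventions matter only for
measure-zero boundary rows in real data but make the implementation exact
and testable.

The 80% identity cut mirrors the discontinuity in average nucleotide
identity that separates picocyanobacterial clades; the synthetic read model
reproduces it by keeping cross-clade identity bands strictly below 80%.

## Community profiling and clustering

Assignments roll up to clade-level categories: strain/subclade counts
aggregate into their clade; SC 5.2/5.3 strains roll up to their subcluster;
reads resolved only to SC 5.1 form category `5.1`; genus-level reads form
`Syn`. Raw counts are divided by the mean genome length (Mbp) of the
category's member strains — for the coarse categories (`5.1`, `Syn`,
subclusters) the mean is over all strains of that subtree, the same
estimator applied at a coarser rank. Stations whose summed normalized count
falls below 600 reads/Mbp are removed (inclusive boundary: exactly 600 is
kept). At a 242 bp mean read length this floor corresponds to about 14.5%
genome coverage (600e-6 × 242); figures near 16% sometimes quoted for the
same threshold do not follow from this formula. Remaining rows are
total-sum scaled to relative abundances.

Bray-Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) is computed on the
relative abundances over the full category set including `5.1`/`Syn` (they
are part of the displayed composition; the caller can drop them first if
desired). Stations are clustered by UPGMA — iterative merging of the
closest pair, inter-cluster distance the size-weighted mean of member
distances. Ties on the minimal distance are broken by the lexicographically
smallest pair of cluster labels (a cluster's label is its smallest member
station id), making the merge order deterministic. The dendrogram exports a
SciPy-style linkage matrix (for cutting, cophenetics and plotting) and a
Newick string whose branch lengths are height differences, so leaf depths
equal merge heights (ultrametric). Cutting by cluster count k picks a
height between the (n−k)th and (n−k+1)th merges; cutting by height keeps
merges at or below it. The default k = 9 mirrors the cluster count used in
the coastal survey this design follows, but both k and height are settable.

Environmental differences among station clusters are tested per variable
(temperature, salinity, distance to coast) with a Kruskal-Wallis test
followed by Dunn's pairwise z-tests on joint ranks with the standard tie
correction. P-values are adjusted with Holm's method by default (`bh` and
`bonferroni` available). The compact letter display is built from the
maximal cliques of the graph whose edges connect clusters *not*
significantly different at adjusted p < 0.05: clusters share a letter iff
they lie in a common clique, so any two clusters with no shared letter are
significantly different, and every non-significant pair shares a letter.
Clusters need at least two non-missing values to enter a test; a variable
with fewer than two such clusters is reported "not testable". All-constant
input is reported as H = 0 with a single shared letter (the rank test is
undefined there, and nothing can differ).

## Growth rates and the CTMI model

Exponential growth dN/dt = μN makes μ the OLS slope of ln N(t) during the
exponential phase. When no window is given, the package scans contiguous
windows of ≥ 4 points (≥ 3 for three-point curves) and keeps the
positive-slope window with maximal R², ties going to the longest then
earliest — this keeps stationary-phase points from diluting the slope.
Cultures with no growing window (flat or declining) contribute μ = 0, which
is the model's own prediction outside the viable range; negative slopes are
clamped to 0 and logged.

The rate-temperature response is the Cardinal Temperature Model with
Inflection (CTMI):

    μmax(T) = 0                 for T ≤ Tmin or T ≥ Tmax
    μmax(T) = μopt · φ(T)       for Tmin < T < Tmax

    φ(T) = (T−Tmax)(T−Tmin)² /
           ((Topt−Tmin)·((Topt−Tmin)(T−Topt) − (Topt−Tmax)(Topt+Tmin−2T)))

with φ(Topt) = 1 identically. Parameters: Tmin, Topt, Tmax (°C) and μopt
(day⁻¹), constrained to Tmin < Topt < Tmax and μopt ≥ 0.

Fitting minimises the residual sum of squares with bounded least squares
(SciPy trust-region reflective) in the reparameterisation
(Tmin, Topt−Tmin, Tmax−Topt, μopt), which turns the ordering constraint
into positivity bounds (minimum gap 0.5 °C). Twenty starting points come
from a Latin hypercube over Tmin ∈ [−20 °C, min T observed], Topt across
the observed range, Tmax up to max T + 10 °C, and μopt up to twice the
maximal observed rate; the lowest-RSS solution wins, ties to the first
start, making the fit deterministic given its seed and invariant to
observation order. Replicates are averaged into per-temperature means
before fitting by default (`--fit-on replicates` fits all points). When no
sub-Tmin observations exist, Tmin is unidentifiable and runs to its search
bound without disturbing Topt/Tmax — the expected behaviour for
acclimation grids that start above the strain's cold limit.

**Confidence intervals** are percentile bootstrap (B = 1000 by default):
replicate rates are resampled with replacement within each temperature and
the model refitted from the full-data estimate. One correction is applied:
the deviation of each resampled per-temperature mean from the observed mean
is inflated by √(n/(n−1)). With n = 3 replicates the naive bootstrap
variance of a group mean is shrunk by (n−1)/n = 2/3, and in coverage
simulations the uncorrected intervals covered the true Topt only ~83% of
the time at nominal 95%; with the standard small-cluster rescaling the
measured coverage is 91–94%. If more than half the refits fail the CI is
reported unavailable rather than fabricated.

## Synthetic data

The generators emulate the statistical structure the analysis consumes, not
sequences: hits are drawn directly as (identity, aligned length, bit score)
tuples, with bit score the monotone stand-in 2·L·(identity/100 − 0.5)
floored at 30. Defaults encode the study conditions the design targets:
reads of mean length 242 bp (SD 15, minimum 100); identity bands
within-strain 97.5–100%, within-clade 95–96.5%, cross-clade 70–78%,
outgroup 65–75% (ordered within-strain ≥ within-clade > cross-clade, with
the cross-clade band below the 80% cut); a configurable fraction of reads
planted to fail each pass-1 filter (outgroup best hit, low coverage, high
e-value) with the plan returned for exact bookkeeping checks; 20% of reads
made deliberately ambiguous between two same-clade strains to exercise the
LCA. Station surveys draw per-station compositions from Dirichlet
perturbations (concentration 200) of regime compositions — by default a
cold regime (12 ± 1.5 °C) dominated by clades I/IV and a warm regime
(25 ± 1.5 °C) dominated by clades II/III, mirroring the cold/warm
thermotype split — with 10 stations and 3000 reads per regime, and
optionally plants shallow stations below the 600 reads/Mbp floor. Growth
curves follow N(t) = N₀·exp(μ(T)·t) capped at a carrying capacity
(N₀ = 10⁶, K = 5·10⁸ cells/mL), μ(T) from the CTMI response, multiplicative
lognormal noise of CV 5%, on an acclimation grid of 10–31 °C in 3 °C steps
with triplicates sampled daily for 14 days.

What this does not emulate: sequence evolution, chimeras, sequencing error
profiles, length-dependent alignment pathologies, uneven genome databases,
or covariation between abundance and environmental variables beyond the
regime structure. Passing recovery benchmarks therefore demonstrates that
the *assignment and clustering logic* is correct under the assumed
statistical structure, not that the upstream alignment step would achieve
the same accuracy on real metagenomes.

## Problem sizes and determinism

The bundled benchmarks (test suite and `scripts/acceptance.py`) use
problem sizes chosen to characterise each method adequately on a single
CPU: 1,000 random LCA queries over 50 random taxonomies; 10,000 simulated
reads for assignment recovery; 100 random 8-station matrices for the UPGMA
oracle; 20 stations for regime recovery; 100 simulated strains for Topt
RMSE; 200 simulations × 200 bootstrap replicates for interval coverage.
All randomness flows through seeded NumPy generators (per-station substreams
spawned via `SeedSequence`), so identical configuration and seed give
byte-identical output files.

## Known limitations

* Category labels are global: one clade label cannot appear under two
  subclusters in the same taxonomy file.
* Percentile bootstrap intervals inherit the usual small-sample caveats;
  with ≤ 2 replicates per temperature the rescaling degenerates and
  intervals may still undercover.
* The automatic exponential-window search assumes a single exponential
  phase; diauxic or lagged curves should be fitted with explicit windows.
* Dunn's test uses the large-sample normal approximation; for clusters of
  fewer than ~5 stations its p-values are approximate.
* `Tmin` estimates are reported but rarely identifiable from acclimation
  grids that do not bracket the cold limit; treat them as bounds.
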