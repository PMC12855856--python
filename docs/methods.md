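# Methods

## Statistical model of residue coupling

The unit of observation is a trajectory's per-residue RMSF vector (nm). The
analysis treats the n trajectories (both peptide conditions pooled; n = 26
for the canonical 13-pair design) as exchangeable samples and asks, for each
residue pair, whether their RMSF magnitudes co-vary monotonically. Spearman's
ρ_s is used rather than Pearson because RMSF is strictly positive,
right-skewed, and the coupling hypothesis is monotone, not linear. Ties are
resolved by average ranks; residues with constant RMSF vectors are flagged
degenerate, their correlations set undefined, and they are excluded from
testing and clustering.

Each ρ_s is mapped to t = ρ_s·√((n−2)/(1−ρ_s²)), a strictly monotone
transform on (−1, 1). Significance comes from a permutation null: each
resample independently permutes two sequential integer arrays 1..n,
correlates them, and converts to t. Because Spearman depends only on ranks,
sequential integers are fully general for tie-free data, and only the
*relative* permutation matters — which is why the exhaustive reference
distribution for small n enumerates the n! relative permutations. The null
is built once and shared across all residue pairs. Defaults: 1e5 resamples
(p-value floor 1/(1e5+1) ≈ 1e-5); the production-scale figure of 5e7 is
reachable through `null_resamples` and is generated in bounded-memory
chunks.

Numerical choices:

- **p estimator.** (count + 1)/(N + 1) for Monte-Carlo nulls (never zero);
  exact count/N when the null is exhaustive.
- **|ρ_s| = 1.** t is infinite; a signed ±inf sentinel orders above every
  finite null value, giving the minimum attainable p.
- **Boundary atoms.** Observed and null statistics of the same rank
  configuration may differ by a few ulps (different floating-point paths),
  so the tail count uses a 1e-10 relative tolerance; without it, atoms of
  the discrete permutation distribution fall out of the count and p-values
  at small n are badly anti-conservative relative to enumeration.

Multiple testing uses Benjamini–Hochberg at q = 0.05 over the upper-triangle
p-vector (delegated to statsmodels; tests verify it against a direct
step-up implementation). A coupling is reported only when p_adj < 0.05 *and*
|ρ_s| ≥ 0.5; the magnitude filter discards weak-but-significant couplings
and is vacuous on datasets where every BH-significant pair already exceeds
0.5.

Condition effects at single residues use an exact paired Wilcoxon
signed-rank test, pairing the two trajectories that share a crystal copy.
The implementation enumerates the 2^n sign assignments via dynamic
programming over the signed-rank sum, with average ranks on tied |d|
(ranks scaled ×2 to integers, so midranks stay exact). Zero differences are
dropped by default (classical Wilcoxon convention, count logged); Pratt
handling is available by flag. Exactness is bounded to ≤ 25 informative
pairs. The two-sided p is 2·min(tail probabilities) capped at 1.

The immunogenicity screen computes, per residue, the rank-biserial
correlation r_rb = 2U/(n₁n₂) − 1 between RMSF and condition (proline taken
as the more-immunogenic group), then permutation-tests the top-k residues by
|r_rb| with condition-label shuffles, using r_rb itself as the statistic
(any U-monotone statistic is decision-equivalent two-sided; one-sided
alternatives are exposed, two-sided is the default since the direction is
not prespecified for arbitrary residues).

UPGMA clustering on the distance 1 − ρ_s of the ranked data offers a
network-free view of coupling structure; the reported cut is the smallest
cophenetic height at which the focal residue joins a cluster of size ≥ 2.

## Network construction and validation

Nodes are all interface residues with their Cα coordinates (Å) from the
reference structure. An edge (u, v) exists iff the coupling is significant
and r_Cα[u,v] < t, with weight |ρ_s|/r_Cα^n; θ (no edge) otherwise. Graph
traversal uses cost 1/weight so that strong coupling means short paths;
the F-metrics below always measure *through-space* Cα distance, not
traversal cost.

One minimum-cost Dijkstra path is kept per ordered node pair. Ties are
broken toward the lexicographically smallest node sequence (heap entries
carry the path, so tuple comparison resolves equal costs deterministically).
Ordered (directed) path counting is the default because F2's defining
comparison is direction-asymmetric. Per path P = (v_start, …, v_end):

- f1 = 1 iff some edge's r_Cα exceeds r_Cα(v_start, v_end);
- f2 = 1 iff some interior node's step to its successor is longer than its
  step from its predecessor (adjacent steps only — the formula, not the
  looser "relative to all previous nodes" phrasing, is implemented);
- f3 = 1 iff some interior node is farther from v_end than v_start is.

All three quantify geometric detours: in a physically sensible coupling
network, shortest paths should hug the structure. F_k is the mean flag over
all paths; single-edge paths contribute 0 by construction. The scan builds
one network per (n, t) grid cell (defaults n ∈ {0, 0.5, 1, 2},
t ∈ {6, 8, …, 52} Å) and the selection rule picks, among rows with
LCC fraction > 0.9, the minimum F1, breaking ties toward smaller n (lower
edge-weight complexity) then smaller t. When no row satisfies the LCC
constraint — typical for sparse synthetic studies where only planted blocks
are coupled — the best-effort row is returned explicitly flagged, and the
full ranking is emitted so a human can override.

## Topology

Degree and k-coreness are computed on the unweighted skeleton; betweenness
and closeness use cost 1/weight; eigenvector centrality uses the raw weight
and is normalized to unit maximum. Closeness on disconnected graphs uses the
component-scaled (Wasserman–Faust) convention, since real coupling networks
leave nodes outside the largest component; a harmonic variant is available
by flag. Community structure is a consensus over independently seeded
Louvain runs (weighted modularity, resolution 1.0 by default, exposed):
partitions are canonicalized to sets of node sets before counting, so label
permutations of one solution are never double-counted. Reported are the most
frequent partition with its recurrence share and, per residue, the frequency
of sharing a community with the focal residue. The recurrence share of the
top partition is implementation- and seed-semantics-sensitive, so it is
reported, never asserted. Default 1e4 iterations; 1e6 via configuration.

## Synthetic studies

The generator emulates the paired design: per residue i, pair k, condition
c, RMSF = exp(μ_i + β_i·z + γ_i·Δ_c + ε), with Δ_P = +½, Δ_V = −½ (so γ_i is
the full V→P log-effect), ε ~ N(0, σ²) i.i.d., and z ~ N(0,1) the copy
effect shared by both conditions of a pair. For members of a planted coupled
block, z is drawn once per (block, pair) — the shared factor is what couples
their fluctuations across trajectories; every other residue draws its own z
per pair, which preserves the paired structure that the Wilcoxon test
exploits without inducing cross-residue correlation. The log-scale model
keeps RMSF positive, and Spearman statistics are invariant to the
exponential, so significance calibration is unaffected by it.

Defaults (unitless log-scale effects; baselines exp(μ) ≈ 0.10 nm heavy
chain, 0.13 nm peptide, typical backbone RMSF magnitudes): σ = 0.2,
background β = 0.1. The default study plants (a) a strong mixed-sign block —
p3 with γ = β = −0.4 coupled to seven second-helix residues at γ = β = +0.4,
mirroring a mutation site that loses dynamics while its coupled partners
gain; (b) a weak 5-residue block at 0.15 that deliberately stays below the
significance threshold; (c) solo condition effects at p4 (0.15) and p6
(0.20). Block members carry the copy effect at the same magnitude as the
mutation effect and sign-linked to it; with σ = 0.2 this puts within-block
correlations near 0.83 — detectable but not saturated at 13 pairs — while
the condition effect alone (two clusters ±γ/2) would cap rank correlations
near 0.5 and make block recovery impossible under BH at genome-of-pairs
scale; the coupling in this model genuinely lives in the shared factor, with
the mean shift superimposed.

What the generator does *not* emulate: spatial autocorrelation of dynamics
(couplings are planted on arbitrary residue sets, not constrained to be
geometric neighbors), heavy-tailed or heteroscedastic RMSF noise,
autocorrelation-induced effective-sample-size loss within trajectories, and
any physical relation between geometry and fluctuation. Passing tests
therefore demonstrate statistical correctness and calibration of the
pipeline, not that real MD data satisfies its assumptions. The idealized
geometry (two antiparallel helical arcs, 1.5 Å rise, 2.3 Å radius,
100°/residue, 18 Å apart, flanking a 9-residue strand at 3.5 Å spacing) is a
cartoon of a class-I binding platform at 90 residues per helix, so its
overall span (~135 Å) is longer than a real groove; distance thresholds in
synthetic tests are set relative to this geometry.

## Problem sizes in the test suite and acceptance script

The shipped suite and `scripts/acceptance.py` run at desk scale, chosen as
the package's own verification conditions: permutation nulls of 1e5
resamples (exhaustive enumeration as reference at n ≤ 6), 50 pure-noise
replicates for FDR calibration, 25 replicates for planted-block recovery
(γ = 0.4, σ = 0.2, 13 pairs, 8-residue block), 400 random geometric graphs
(≤ 8 nodes) for the brute-force Dijkstra/F-metric oracle, and consensus
community runs of 40–500 iterations. Production-scale settings (5e7
resamples, 1e6 Louvain iterations) are plain configuration changes.

## Known limitations

- Exact Wilcoxon is limited to 25 informative pairs; larger designs need a
  large-sample approximation that is deliberately not provided here.
- The permutation null assumes exchangeable trajectories; systematic
  copy-level differences in overall mobility violate this and inflate
  couplings (mitigated in practice by the paired design, but not tested).
- Edge significance ignores the dependence among the O(k²) correlation
  tests sharing residues; BH controls FDR under positive dependence, which
  rank correlations of this structure typically satisfy but are not
  guaranteed to.
- The network selection rule inherits the arbitrariness of the > 90% LCC
  constraint; the full scan table is always emitted for transparency.
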