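# Methods

## Overview

`fracnet` reconstructs group-level *structural covariance networks* from
regional brain morphometry and compares their graph-theoretical
organization between two groups. The morphometric descriptor is the
three-dimensional box-counting fractal dimension (3D-FD) of each
region's voxel mask; the network nodes are parcellated regions (97
after merging the 26 cerebellar atlas labels into 7 lobes within a
116-region parcellation) and an edge is a statistically reliable
positive inter-regional correlation of 3D-FD across the subjects of a
group. Because each group yields exactly one network, group inference
rests on label permutation rather than subject-level statistics.

## Box-counting fractal dimension

For a binary mask, the volume is tiled by cubic boxes of side `s`
anchored at the array origin; partial boxes at the far faces count if
they contain foreground. With `N(s)` the number of occupied boxes, the
fractal dimension is the OLS slope of `log N(s)` against `log(1/s)`.

Numerical choices:

- **Size schedule.** Powers of 3 from 1 up to the largest extent of the
  region's bounding box (powers of 2 available via `base=2`). The
  triadic schedule makes the Menger-sponge oracle exact:
  a level-L sponge gives `N(3^k) = 20^(L-k)` and slope
  `log 20 / log 3 ≈ 2.7268` with `r² = 1`.
- **Fit range.** Sizes are used from the smallest up to the largest
  size whose count still exceeds 1; once the count saturates at 1 it
  carries no scaling information. At least 3 informative sizes are
  required, otherwise the region is flagged rather than fitted.
- **Small regions.** Regions under 27 voxels are flagged as missing
  (`fd = NaN`) instead of being reported as zero; the log-log fit is
  meaningless there.
- **Grid origin.** A single origin at the volume corner. Offset
  averaging would smooth counts for irregular masks but breaks the
  exact closed forms used as oracles; the estimator's recovery error on
  known fractals is well inside the 0.05 tolerance without it.

Fitted dimensions of 3-D masks land in [0, 3] up to fit tolerance:
solid cube 3, one-voxel sheet 2, line 1.

## Network construction

Per group, with regions × subjects FD values:

1. **Covariate removal.** Each region's values are replaced by
   residuals of OLS on [intercept, age, sex]. A covariate constant
   across subjects is dropped with a warning. Correlations of
   residuals are invariant to affine transformations of the
   covariates.
2. **Correlation.** Pearson r for every region pair across subjects;
   two-tailed p from the t transform with n−2 df. Zero-variance
   regions are flagged and can never form links.
3. **Thresholding.** Negative and diagonal entries never become links.
   Three gates are provided: raw `p ≤ α`; Benjamini–Hochberg FDR at
   level α over the n(n−1)/2 upper-triangle p-values; and the
   two-stage rule `p ≤ 0.05` followed by keeping the 20% of all
   possible links with the largest surviving r. The 20% is read as a
   fraction of all n(n−1)/2 pairs (not of the survivors); with 97
   nodes that is floor(0.20 × 4656) = 931 links when enough pairs
   survive the gate. Ties at the cutoff r are broken toward the
   lexicographically smaller (i, j) pair for determinism. The
   two-tailed p convention is the default throughout.

## Graph metrics

All metrics operate on the binary undirected adjacency matrix. Degree,
density (percent of the n(n−1)/2 possible links), largest-component
size (an isolated node is a size-1 component), unweighted shortest
paths (∞ across components), triangles `t_i = (A³)_ii / 2`, clustering
`c_i = 2 t_i / (k_i (k_i − 1))` with `c_i := 0` for degree < 2 (the
convention that avoids 0/0), betweenness centrality normalized by
(n−1)(n−2) over ordered pairs (the star hub scores exactly 1), and
global efficiency `E_glob` = mean inverse distance over ordered pairs
with `1/∞ := 0`.

The characteristic path length admits three conventions because
covariance networks are routinely disconnected:

- `harmonic` (default): `L_p = 1 / E_glob`, the reciprocal of the mean
  inverse distance — finite whenever any pair is connected;
- `finite_mean`: arithmetic mean of finite distances over connected
  ordered pairs;
- `lcs_mean`: `finite_mean` restricted to the largest component.

The harmonic convention is the default because it is the one that
remains well-defined under fragmentation, but published tables in this
literature do not always satisfy `L_p × E_glob = 1`, which suggests a
finite-mean-style convention in some sources; all three are exposed and
the identity `L_p × E_glob = 1` is guaranteed only for `harmonic`.

Small-world structure is considered estimable only when the mean degree
exceeds `ln n` (natural log; `ln 97 ≈ 4.574`); the flag is carried in
the global-metrics output.

**Null model.** Maslov–Sneppen double-edge swaps: two links (a–b, c–d)
are rewired to (a–d, c–b) when this creates no self-loop or duplicate
link, preserving every node's degree exactly. The default targets 10
successful swaps per link with an attempt cap of 100× the target;
rigid graphs (complete graphs, stars) are returned unchanged with a
warning. Ensembles of rewired graphs supply the mean ± sd baseline for
`L_p`, `C_p`, `E_glob`; a ring lattice loses most of its clustering and
path length under rewiring, the contrast that defines small-worldness.

## Group inference

Observed statistic: metric(network A) − metric(network B). Null:
subjects are pooled and reassigned at random to two groups of the
original sizes; both networks are rebuilt per shuffle and the
statistic recomputed. By default age/sex residualization is repeated
inside every shuffle (the statistically cleaner order, since the
covariate fit is part of the pipeline being tested); pre-residualizing
once on the pooled table is available via `residualize_mode="once"`.
The decision rule is one-tailed: the difference is significant when it
exceeds the 95th percentile of its null distribution (or falls below
the 5th, for metrics hypothesized to increase in the weakened group,
i.e. path length). Permutation p-values use the +1 correction, so the
smallest attainable p is 1/(n_perm+1) — nodal results at p < 0.001
require at least 1,000 shuffles.

Per-node betweenness differences run through the same machinery; the
reported table is the top-k regions by betweenness decrease among
those with permutation p below the cutoff.

Threshold sweeps evaluate both groups over a grid of significance
levels (default 0.05 down to 0.001); empty networks at tight levels are
recorded with `L_p = NaN` rather than dropped.

`bh_fdr` implements the Benjamini–Hochberg step-up rule directly
(largest k with `p_(k) ≤ k q / m`); the thresholding module uses the
statsmodels implementation, and the two are cross-checked against each
other in the test suite.

## Attack resilience

Nodes are removed one at a time with their incident links; after each
removal, global efficiency and largest-component size are recomputed on
the induced subgraph of the remaining nodes (the node set shrinks — no
padding with isolates, so the relative LCS reaches 0 at full
destruction) and normalized by the intact network's values. Targeted
attacks remove in descending betweenness order, ranked once on the
intact network by default (`rank_mode="static"`); dynamic re-ranking
after every removal is available. Ties are broken by higher degree,
then node index. Random attacks average the curves of (by default) 100
uniformly shuffled removal orders. The efficiency ratio of the last
two or three surviving nodes is a ratio of near-binary outcomes and
remains noisy at any practical ensemble size; the curves are meaningful
while a non-trivial subgraph remains.

## Synthetic data

The generator provides the two kinds of inputs the pipeline needs and
nothing more.

**Fractal volumes** are deterministic constructions with known
dimension (Menger sponge, cube, sheet, line) used to validate the FD
estimator against closed forms.

**Cohorts** follow a Gaussian latent-factor model. Region i of subject
j in a group takes

```
value = baseline + β_age·age_j + β_sex·sex_j
        + g·G_j + λ_b·F_{b(i),j} + ε_ij ,
```

with one global factor `G` per subject, one factor `F_b` per region
block, independent Gaussian noise, ages uniform on [30, 70] years and
sex Bernoulli(0.5). The group effect is a uniform reduction of the
loadings (`g`, `λ_b`) in group B, which weakens all positive
correlations and left-shifts the coefficient distribution. The global
factor is what gives the coefficient distribution a positive mean, as
a shared anatomical scale factor does in real morphometry; without it
a control network would be connected across blocks only by chance
correlations, and the expected ordering of component sizes between
groups would not be stable.

The default two-group design mirrors the target study's geometry: 40
subjects per group × 97 regions, eight 10-region blocks, loadings
chosen so that group A's mean off-diagonal correlation is ≈ 0.16 and
its within-block correlations survive p = 0.001 at n = 40, while group
B's (loadings scaled by ≈ 0.55) mean is ≈ 0.09 with within-block
correlations that drop out as the threshold tightens. The resulting
group-A network has ~20–25% density at p ≤ 0.05, falling toward 5%
at p ≤ 0.001.

What the generator does *not* emulate: anatomically realistic atlas
geometry or region volumes, MRI intensity artifacts, heavier-tailed or
spatially autocorrelated noise, hemispheric symmetry, or nonlinear
covariate effects. Passing tests therefore demonstrate that the
pipeline recovers planted covariance structure and calibrates its
error rates under a well-specified Gaussian model — not that any
particular clinical dataset would show these effects.

The null design used for type-I calibration is 30 regions × 20
subjects per group with identical parameters in both groups; every
rejection is a false positive. The permutation decision rule's
empirical rejection rate sits at the nominal 5% (the acceptance script
recomputes this from scratch with 200 replicate pairs at n_perm = 200,
a deliberately scaled-down replicate/shuffle count that keeps the
experiment at desk scale while leaving the Monte-Carlo error on the
rate near ±0.015).

## Randomness and reproducibility

Every stochastic routine takes an explicit seed. A root seed fans out
to per-stage substreams (`numpy.random.SeedSequence.spawn`), so stages
are independently reproducible; the pipeline manifest records the
config, the derived stage seeds, and a SHA-256 checksum of every output
file, and a rerun from the same config reproduces the checksums.

## Known limitations

- Box counts use a single grid origin; FD estimates for masks far from
  self-similar carry fit error that the `fit_r2` field exposes but the
  pipeline does not act on.
- The 20%-of-largest-coefficients rule has two defensible readings
  (fraction of all pairs vs fraction of survivors); the first is
  implemented as the default and the gate's α is configurable, but
  results under the two readings differ at low survivor counts.
- Betweenness ranks in targeted attacks are computed on the binary
  graph; weighted variants are out of scope.
- Permutation tests assume exchangeability of subjects across groups
  after covariate removal; confounds that differ between groups in
  distribution (not just in mean) violate this.
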