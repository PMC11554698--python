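# Methods

## The measure: nodal assortativity

Degree assortativity `r` of an undirected network is the Pearson correlation
between the degrees of connected node pairs, computed over the directed edge
list (each undirected edge contributes both orientations). Assortative
networks (`r > 0`) concentrate connections among similar-degree nodes and
are robust to targeted edge removal; disassortative ones (`r < 0`) rely on
hubs and are vulnerable to hub failure. Some published forms of the global
coefficient normalize by node count with ambiguous parenthesization; this
package implements the quantity the verbal definition fixes — the
directed-edge-list Pearson correlation — which is also what networkx
computes, and tests cross-check the two.

The global coefficient hides local variation, so it is decomposed per node
through the neighbor-degree disparity:

    delta_i    = (1/d_i) * sum_{j in N_i} |d_j - d_i|
    deltabar_i = delta_i / sum_j delta_j
    r_i        = (r + 1)/m - deltabar_i

with `m` the number of nodes. The decomposition is exact: `sum_i deltabar_i
= 1` and `sum_i r_i = r` (tested to 1e-12 / 1e-9). A node surrounded by
degree-disparate neighbors (a locally "hub-like" or "leaf-like" position)
gets a low, possibly negative `r_i`.

Conventions at the edges of the definition:

- **Degrees** default to binary degrees on the network binarized at
  `|weight| > 0` ("number of neighbors"); a `weighted` mode substitutes node
  strengths. Negative functional weights count by magnitude — a strong
  negative partial correlation is still a connection.
- **Isolated nodes** get `delta_i = 0` and stay in the vector, so its length
  always equals the atlas size.
- **Regular graphs** (all disparities zero) leave `r` undefined;
  `deltabar_i` is set uniformly to `1/m` to preserve its unit sum and the
  `r_i` are returned as NaN with a `degenerate` flag rather than silently
  numeric.
- **Comparison measures**: clustering coefficient (binary triangle density;
  weighted mode is the Onnela geometric-mean variant on `|weights|` rescaled
  by the maximum), betweenness centrality (unnormalized Brandes counting
  over unordered pairs; weighted mode uses edge length `1/|weight|`), node
  strength (`sum |weights|`), node degree. The star `K_{1,k}` center has
  betweenness `C(k, 2)` under this convention.

## Functional-network inference

A parcel's summary signal is the principal left singular vector of its
time × voxel BOLD block (first temporal principal component), sign-aligned
with the voxel mean. Edges are partial correlations estimated by node-wise
elastic-net regression of each standardized parcel signal on all others
(`l1_weight` 0.5 by default); the two directed coefficients are combined by
a sign-consistent geometric mean, zero on disagreement (an "and"-rule
symmetrization that guarantees symmetry and conservative sparsity). In the
zero-penalty limit this reproduces the analytic partial correlations
`-Omega_ij / sqrt(Omega_ii Omega_jj)` (tested at 0.05 tolerance against a
known 3-variable precision matrix).

When no penalty is given, each regression selects its own penalty by 5-fold
cross-validation on a log-spaced grid (1e-3 to 1, 20 points) with the
**one-standard-error rule**: the CV-minimum penalty optimizes prediction and
systematically under-sparsifies (in our recovery checks it kept roughly half
of its reported edges as tiny false positives), so the largest penalty whose
CV error is within one standard error of the minimum is used instead, the
standard practice when support matters. At 20 parcels × 200 timepoints
(the study-scale volume count) support recovery against known sparse
precision matrices reaches Matthews correlation ≈ 0.7–0.9 per draw in the
acceptance checks.

## Synthetic cohort generator

The generator emulates the *data structure* of a three-stage
cognitive-decline cohort, not its biology: 24 SCI / 46 MCI / 18 ADD
subjects; ages from group-specific truncated normals (56.95 ± 7.54,
62.04 ± 9.78, 69.83 ± 8.52 years on [40, 95]); sex balanced per group and
unused by the pipeline; a Schaefer-style 400-node label table (L/R split,
seven canonical systems).

**Base networks.** Each node has a lognormal expected-connectivity template
(sd 0.45 in log units) shared across subjects with 10% per-subject jitter —
a parcel's hubness is a property of its atlas position. Edges are Bernoulli
draws with probability proportional to the product of endpoint propensities
times a degree-similarity kernel `exp(-beta |t_i - t_j| / mean(t))`:
`beta = +2.5` for structural networks (assortative, median global r ≈ +0.3)
and `beta = -0.5` for functional ones (median r ≈ -0.1), reproducing the
sNET-assortative / fNET-disassortative dichotomy at 10% density. Structural
weights are lognormal (fiber-count-like); functional weights are uniform
magnitudes 0.1–0.4 with 70% positive sign (partial-correlation-like).

**Planted effects.** Stage effects are realized through topology: at each
designated hypo node, MCI and ADD subjects have edges rewired toward hubs
(raising neighbor-degree disparity, lowering `r_i`); at disjoint hyper
nodes, ADD subjects are rewired toward degree-similar partners (raising
`r_i`). `effect_size` (default 1.0) is the target *group-mean contrast* in
units of the pooled baseline standard deviation of `r_i` at that node: the
per-subject rewiring budget absorbs the cohort's baseline group-mean
fluctuation, so every generated cohort carries the nominal contrast
(realized within a few percent) rather than the nominal contrast plus
±0.25 sd of group-sampling noise — the standard construction for
power-calibrated benchmarks. Since each move also perturbs neighbor degrees
and the disparity normalization, the realized shift is measured exactly and
corrective passes absorb the residual to within 5% per subject. Planted
nodes are assigned the median template propensity so both directions of
rewiring are feasible at every seed. Node degree at the planted node is
preserved by every move, so degree-based measures stay blind to the
planting by construction — the effect lives in degree *mixing*, exactly
where nodal assortativity looks. Configurations whose effect cannot be
realized at the requested density raise an explicit infeasibility error
rather than silently under-delivering.

**BOLD panels.** For closing the loop with the inference module, a subject's
functional network is converted to a precision matrix `I - W`, diagonally
loaded to keep the smallest eigenvalue at 0.05 and renormalized to unit
diagonal (support preserved, magnitudes shrunk), and 200-timepoint Gaussian
series are drawn from its inverse.

**What the generator does not emulate.** Spatial embedding and hemispheric
symmetry; between-node correlation of nodal measures beyond what the shared
degree template induces; heavy-tailed subject outliers; scanner/site noise;
any coupling between age and the planted effect (an `age_confound` knob
exists but defaults to 0, mirroring the negligible age correlation in the
study). Passing tests therefore show the *procedure* behaves as claimed
under clean planted effects — they say nothing about effect sizes in real
cohorts.

## Identification and verification pipeline

Stage 1 ranks nodes by Welch's unequal-variance t-test between the two
groups of a task (SCI-vs-MCI, MCI-vs-ADD, and SCI-vs-ADD for the grid),
keeps `p <= 0.05`, sorts by ascending p (ties: larger |t|, then lower node
id) and selects the top k = 5. No multiple-testing correction is applied by
default — calibration is delegated to the shuffle null and classifier
verification — but Benjamini-Hochberg is available behind a flag. Nodes
where both groups are exactly constant get the degenerate convention
(p = 0 if the means differ, else 1) with a warning.

Stage 2 verifies the selection with leave-one-out linear-SVM accuracy
(C = 1.0, standardization fit on each training fold; both are free choices
of such protocols, fixed here for reproducibility and echoed in every
result). The default protocol selects nodes once on all subjects and then
runs LOO — the double use of data the shuffle null is designed to expose; a
nested mode re-selects within every training fold for unbiased estimates.

**Shuffle null.** Labels are permuted within the task's subject pool
(preserving the 24/46 marginals), and the ranking + selection + LOO loop is
re-run per permutation. Where the re-selection happens was a genuinely open
design point, and the two readings differ enormously:

- *per-shuffle* selection (once on all subjects, then LOO) lets the held-out
  subject leak into the selection; with 400 candidate nodes and ~70
  subjects this inflates the null to ~0.75 mean accuracy for *any* data —
  it measures the leakage bias of the default protocol, not chance.
- *per-fold* selection (inside every LOO training fold) is leakage-free and
  yields a mean near chance (~0.55 at 24-vs-46; the residual above 0.5 is
  the majority-class lean of a soft-margin SVM under class imbalance).

Published chance baselines for this kind of pipeline sit at ~0.50
across tasks with very different class imbalances, which is only consistent
with the leakage-free variant; `shuffle_null` therefore defaults to
`selection="per_fold"`, with `"per_shuffle"` available explicitly. 200
shuffles by default (SEM < 0.01).

**Age diagnostics.** Per selected node, a simple linear regression of the
measure on age reports Pearson r, R² and the slope F-test p (identical to
the slope t-test in simple regression). The age-augmented comparison runs
the LOO once with and once without age as an extra feature and pairs the
per-fold correctness indicators in a paired t-test — deterministic, and
conservative where repeated-subsample designs proved anti-conservative —
plus the ratio |age weight| / min |other weight| from a full-data fit.

## Numerical and engineering choices

- Adjacency I/O: headerless CSV written at `%.17g` (exact double round
  trip) or MatrixMarket symmetric coordinate format (lower triangle).
- Symmetry is validated at 1e-10 and inputs re-symmetrized exactly;
  diagonals forced to zero.
- All randomness flows from `numpy.random.SeedSequence` spawns of a single
  config seed; cohorts, panels, shuffles and reports are reproducible
  byte-for-byte given the seed, and every experiment report embeds a config
  hash.
- Generator-internal assortativity uses an O(n²) degree-moment form of the
  directed-edge Pearson correlation (algebraically identical; tested
  against the measures module).
- The acceptance sweeps run the full 400-node, 88-subject study geometry;
  100-seed power and calibration sweeps generate structural networks only,
  which are bit-identical to the structural half of a two-modality cohort
  by seed construction.

## Known limitations

- Because the planted contrast is calibrated per cohort, the generator's
  group difference at planted nodes is conditionally near-deterministic;
  real effects would also fluctuate across cohort draws. Power estimates
  from these sweeps are therefore for the stated contrast exactly, not for
  a population effect re-sampled per study.
- Small, dense configurations (tens of nodes) cannot absorb large disparity
  shifts and will raise infeasibility errors at `effect_size` 1.0; reduced
  examples use 0.5–1.0 depending on geometry.
- The per-fold shuffle null retains a majority-class lean above 0.5 that
  grows with imbalance (~0.56 at 24/46, ~0.62 at 46/18); it is a property
  of soft-margin SVMs under label permutation, not a bug in the null.
- Weighted betweenness/clustering modes are provided but the study-analog
  pipeline runs on binarized degrees; no attempt is made to resolve which
  the source analysis used.
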