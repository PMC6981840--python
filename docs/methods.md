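# Methods

## Scope and model

`coexrewire` analyses a probes × samples matrix of RMA-normalised log2
microarray intensities together with per-subject dated diagnosis records
(labels NC, MCI, AD). Its outputs are (a) a filtered probe set, (b) a
per-probe direction-of-expression table versus NC, (c) six signed Pearson
co-expression networks per threshold (3 states × 2 signs), (d) a per-node
rewiring score across the state networks, and (e) a consensus differential
network of the condition states against the NC reference.

## Diagnosis assignment

Each sample carries a subject ID and a collection date (encoded in the
sample ID as `<subject>_<YYYYMMDD>`). The assigned label is the diagnosis
record minimising |exam date − collection date|; exact ties are broken
toward the **earlier** exam record so the merge is deterministic. Samples
whose subject has no record are dropped with a warning rather than failing
the run, since expression files routinely contain more arrays than curated
diagnoses.

## Scale handling

RMA output is log2. All filtering and correlation calculations run on the
linear intensity scale obtained by x → 2^x; the matrix container carries an
explicit scale flag and `delog` refuses to exponentiate twice. Pearson
correlation is not invariant under the exponential map (a planted log-scale
correlation of 0.8 attenuates to ≈ 0.79 at the noise level used here), so a
config switch (`FilterConfig.anova_on_log2`, and log2 input generally) is
available for users who prefer log-scale statistics; linear is the default.

## Probe filter

Stage 1 (variation/intensity, linear scale, all samples pooled):

* coefficient of variation sd/mean ∈ [`cv_min`, `cv_max`] = [0.7, 10],
  using the sample (n−1) standard deviation; a zero-mean probe has
  undefined CV and is excluded with a flag;
* at least `min_frac` = 20% of samples strictly above
  `intensity_cut` = 100 (strict ">" for the cut, "≥" for the fraction).

Stage 2 (ANOVA): one-way fixed-effects ANOVA per surviving probe across the
three groups, keep p < `anova_alpha` = 0.1. The per-probe F statistic is
computed vectorised (group means and within-group sums of squares); rows
with zero within-group variance get p = 0 if the group means differ and
p = 1 (flagged) if they do not. Stage order is variation/intensity → ANOVA;
the final survivor set is order-independent, only the report's per-stage
counts depend on it. Widening the CV window or lowering the intensity
thresholds can only grow the stage-1 set (monotonicity, covered by tests).

## Direction table

Per probe and contrast (MCI vs NC, AD vs NC): two-sided Welch t-test
(unequal variances, Welch–Satterthwaite df), then Benjamini–Hochberg
adjustment across the retained probes **within one contrast**
(Benjamini–Yekutieli available via `fdr_method`). Direction is the sign of
the linear-scale mean difference. Display bands: direction alone for
adjusted p ≤ 0.1; direction plus the p-value for 0.1 < p ≤ 0.75; a dash for
p > 0.75 (no direction is reported when the evidence is that weak). The
three bands partition [0, 1]. Two constant equal groups return p = 1 with a
warning rather than NaN.

## Networks

Per state, the Pearson correlation matrix of the surviving probes over that
state's samples (≥ 3 samples required; zero-variance probes get correlation
0, flagged). Signed networks use **strict** thresholds: positive keeps
r > T, negative keeps r < −T, so boundary values are excluded and the two
sign classes are disjoint for any T > 0. Edge weights store the signed r.
All retained probes stay in every network's node set even when isolated —
the cross-state comparisons require a common node set. Defaults: T = 0.1
networks feed the rewiring and consensus comparisons (weak correlations
removed but disruption signal kept), T = 0.3 networks describe the plain
per-state co-expression structure.

## Rewiring score

With a_s(v) the adjacency vector of node v in state s — 0/1 entries in
binary mode (default), |r| in weighted mode — and centroid
c(v) = mean_s a_s(v):

    score(v) = Σ_s ‖ a_s(v) − c(v) ‖²

Properties used as test oracles: zero iff the neighbourhoods are identical;
invariant under state permutation; additive over neighbour slots in binary
mode, with a 1-of-3 or 2-of-3 presence pattern contributing exactly
(2/3)² + (1/3)² + (1/3)² = 2/3. Variants: `degree_corrected` divides by the
node's mean degree across states (isolated nodes keep score 0);
`distance` sums unsquared per-state distances. The raw sum of squares is
the default because it is the direct variance reading of "connectivity
variance between networks"; published rewiring tools apply their own
normalisation constants, which are not reproducible without their inputs,
so the family is exposed as configuration rather than guessed. Ranked
tables are cut at score ≥ 5 by default; ties rank lexicographically by node
ID for determinism.

## Consensus differential network

Relative to reference R with condition set C (default: R = NC,
C = {MCI, AD}), per sign class:

* gained = { e : e ∉ E_R and e ∈ E_c for **all** c ∈ C }
* lost   = { e : e ∈ E_R and e ∉ E_c for **all** c ∈ C }

gained ∩ lost = ∅ by construction, and edges changing in only some
conditions appear in neither set. Binary edge presence on the T = 0.1
networks is the default input. Positive and negative edge universes are
never mixed.

## Synthetic data generator

`simdata` emulates the pipeline's inputs. Within each state, samples are
drawn from a multivariate Gaussian in log2 space: probe means are
baseline (default N(8, 1.5²) across probes, matching typical expressed-probe
log2 intensities) plus any planted per-state shift; the within-state
correlation matrix is assembled from configured blocks (uniform pairwise
target r inside a block, optional cross-block targets) and sampled through
its Cholesky factor with marginal sd `noise_sd` (default 0.5). For a single
equicorrelated block this is exactly the one-factor construction
x = √r·f + √(1−r)·ε; the Cholesky route additionally supports negative
targets (bounded by the equicorrelation constraint r ≥ −1/(k−1)) and
cross-block targets, with positive-definiteness checked at sampling time.
Diagnosis tables get one record per subject at the draw date, plus optional
decoy records at configurable offsets to exercise nearest-date assignment.
The ground truth enumerates exactly the planted DE probes, per-state edges
(pairs with nonzero target), the consensus gained/lost sets implied at the
strict |r| > 0.1 threshold, and the node(s) with the most state-varying
adjacency slots.

What the generator does **not** emulate: batch effects, probe-specific
dynamic ranges, heavy-tailed intensity noise, missing values, dependence
between subjects, or the probe-to-gene multiplicity of real arrays.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the assumed Gaussian factor structure, not performance on
real microarray data.

### Recovery scenarios (preregistered conditions)

Two canonical scenarios define the recovery checks; their parameters were
fixed by the power analysis below, before measurement, and are not tuned.
At n = 150 samples/state the Fisher-z null sd is 1/√147 ≈ 0.082, so a truly
uncorrelated pair crosses the T = 0.1 edge threshold with probability
≈ 0.11 per state — a key design constraint.

* **Rewiring** (`rewiring_scenario`): 30 probes, 150 samples/state; one hub
  planted in a different 9-probe equicorrelated block (r = 0.8) per state,
  i.e. 24 distinct partners. Planted binary score 24·(2/3) = 16 versus
  ≈ 9–13 for the strongest competitor including edge noise, so the hub
  should rank first in ≥ 18/20 seeds with margin.
* **Consensus** (`consensus_scenario`): 30 probes split into two 15-probe
  modules; module L has r = 0.8 in NC and −0.05 in the conditions
  (its 105 internal edges are the consensus-lost truth), module G mirrors
  it (105 gained), cross-module pairs carry r = −0.10 in every state.
  The mild anti-correlations are essential: with exactly-zero "absent"
  correlations, per-edge recall of a lost edge is capped at
  (1 − 0.11)² ≈ 0.79 < 0.9 at these settings regardless of planting — edge
  absence at a low threshold is only a recoverable signal when the true
  correlation sits safely below it. Recovery is evaluated per sign class
  (here: the positive differential network against the positive ground
  truth), consistent with the differential comparison itself running
  separately per sign; the borderline negative targets make the
  negative-sign networks intentionally uninformative in this scenario, and
  the negative-sign code path is covered by dedicated tests with planted
  anti-correlated pairs.

The demo scenario (50 probes, 60 samples/state, `noise_sd` = 1.0 so that
linear-scale CVs ≈ 0.8 fall inside the filter window as they do for
expressed probes) plants 20 shifted probes and one NC-only plus one
MCI/AD-only block, giving every pipeline stage visible work at a size that
runs in seconds.

## Numerical and degenerate-input choices

* Correlation matrices are symmetrised, clipped to [−1, 1] and given an
  exact unit diagonal after `np.corrcoef`.
* Strict threshold inequalities everywhere (r > T, r < −T, p < α,
  intensity > cut); fraction and score cutoffs are inclusive (≥).
* Ranking ties break lexicographically by node ID; nearest-date ties break
  to the earlier record.
* Zero filter survivors is a valid empty result (warning, not an error);
  fewer than two surviving probes aborts the network stage with a clear
  message.
* All simulation randomness flows through one `numpy` Generator seeded from
  the config, making every output bit-reproducible.

## Problem sizes

Default test and acceptance sizes — 100-probe × 30-sample filter matrices
(50 replicates), ≤ 10-node graph triples (100 replicates), 30-probe /
150-sample recovery studies (20 seeds), a 2000-probe / 300-sample null for
ANOVA calibration and 50-probe nulls for FDR calibration (20 seeds) — were
chosen so that each check has clear statistical margin while the whole
suite runs in well under a minute per module.

## Known limitations

* The rewiring score's absolute scale is family-specific; compare scores
  only within one run configuration.
* Consensus inference is binary presence/absence; it does not grade edge
  strength changes (a weighted mode exists for rewiring only).
* The ANOVA and Welch stages assume approximately Gaussian linear-scale
  intensities within groups; heavy-tailed real data may warrant the log2
  option.
* Probe IDs are treated as opaque node labels; collapsing multiple probes
  of one gene is out of scope.
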