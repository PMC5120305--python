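# Methods

## Regulation model and design construction

Gene expression is modelled one sampling step ahead: the level of
gene *i* at time *t* is a linear function of an intercept (basal
rate), the gene's own level at *t−1* (self-regulation / degradation),
and the levels of candidate regulators at *t−1*, plus Gaussian noise.
Two choices deserve note.

**Lag in steps, not physical time.** The lag is one sampling
interval, regardless of the actual spacing of time stamps. The
discretization absorbs the interval length into the coefficients, so
non-uniformly sampled series are treated as step-lagged; coefficients
are therefore per-step effects, not rates per unit time.

**Level form.** The response is the expression level at *t*, with
the self-lag as a regressor. Regressing the finite difference
x(t)−x(t−1) instead is an equivalent reparameterization (it shifts
β_self by one); the level form avoids dividing by the interval
length. Rows never span series boundaries, so a design with S series
of T_s points has n = Σ(T_s − lag) observations.

**Self terms.** The self-lag column is always present — in the null
model and every other model — and the target is never offered as a
candidate regulator of itself, nor is any heterodimer containing it.

**Heterodimers.** A heterodimer regulator j:l has activity equal to
the elementwise product of its partners' mRNA levels, computed on the
data's loaded scale. If the data are log-scale the product is still
taken literally (a documented convention: on log scale a product
corresponds to the sum of the partners' log levels scaled into the
exponent). Isoform-level data (e.g. CAGE tag counts) are first
aggregated by summing isoform rows per gene symbol.

## Marginal likelihood

Priors: flat on the intercept, Jeffreys p(σ²) ∝ 1/σ² on the noise
variance, and a Zellner g-prior N(0, c·σ²(X̃ᵀX̃)⁻¹) on all
non-intercept coefficients, with X̃ the mean-centred regressor block
(the flat intercept makes the marginal depend on the data only
through centred quantities). Integrating all three blocks gives

    log p(y|M) = log Γ((n−1)/2) − ((n−1)/2)·log π − ½·log n
                 − (p/2)·log(1+c) − ((n−1)/2)·log Q,
    Q = c/(1+c)·SSE + 1/(1+c)·TSS

The constant in front is kept so the value is a genuine log density;
it cancels across models of one gene. Two conventions in the
literature differ on whether the benchmark constant multiplies or
divides the prior covariance; this implementation uses the
covariance-multiplier form, fixed by two checks that fail under the
other convention: the scale-equivariance identity
log p(k·y) − log p(y) = −(n−1)·log|k|, and agreement with a
10⁷-sample importance-sampled Monte-Carlo integration of
likelihood × priors (relative error well under 5%).

Choices within the scoring:

- **p counts all g-prior regressors**, i.e. |subset| + 1 for the
  self-lag. Counting only the subset would leave the self-lag
  coefficient without a prior and the closed form incoherent.
- **c = max(n, p_total²)** with p_total the gene's total candidate
  count — a dataset-level constant (the benchmark recommendation is
  about the candidate pool, not the per-model size), so all models of
  one gene share one c and their posteriors are comparable.
- **SSE floor** at 10⁻¹²·‖y‖² keeps interpolating fits finite.
- **Singular designs** (duplicated or collinear columns) score −∞ and
  are skipped silently by the search.
- All probability arithmetic is in natural logs; accumulations use
  log-sum-exp. Finite behaviour is exercised for noise levels
  spanning twelve orders of magnitude.

## Structure priors

The default prior is the sparsity power law p(M) = L^−2.66 over the
number of regulators L, with the null model treated as L = 1 so its
prior is finite (the search needs a finite starting threshold).

The binding-evidence prior multiplies, per candidate TF, an
independent Bernoulli term with success probability P_ij = Q_ij·R:
Q_ij ∈ {1, 0.5, 0.05} by consensus-network tier (filtered proximal;
unfiltered-proximal-or-distal only; absent) and R the probability a
TF binds the same position across cell types (default 0.26, a single
global value; public ChIP-seq archives rarely support per-TF
estimation, so the value from the most deeply assayed TF is applied
globally). Members contribute log P_ij, non-members log(1−P_ij), and
the model-size power law is added on top — the two prior ingredients
(which TFs, and how many) combine multiplicatively. With all
P_ij = 0.5 the Bernoulli product is subset-independent and rankings
reduce exactly to the sparsity prior's.

A heterodimer's P is the product of its components' P_ij — an
independence assumption adopted here because binding evidence is
monomer-level. Probabilities are clamped to [10⁻⁶, 1−10⁻⁶] so no
membership event is impossible.

`estimate_peak_reproducibility` offers a per-TF R from K ≥ 2 peak
files: union-merge all intervals (≥ 1 bp overlap) into consensus
regions, count per region the datasets overlapping it, and average
(support−1)/(K−1). It is a consensus-region estimator built for this
package; per-TF use is optional and the global default stands.

## Model search

Per gene: score the null model (intercept + self-lag); its
unnormalized log posterior is the initial cutoff. Each stage scores
every queued subset, accepts those strictly above the cutoff,
accumulates their mass into the normalization constant and into each
member's edge accumulator, raises the cutoff to the stage's best
accepted posterior, and queues all one-regulator extensions of the
stage's accepted subsets (globally deduplicated, never re-scoring an
already-evaluated subset, capped at max_model_size, default
min(10, n−4) to keep n > p + 2). The search stops when a stage
accepts nothing; since the cutoff rises strictly and model size is
bounded, termination is guaranteed, and the whole procedure is
deterministic.

Two deliberate resolutions of underdetermined points:

- **Stagewise vs fixed cutoff.** Raising the cutoff each stage is the
  default; a fixed cutoff (the null's posterior throughout) accepts a
  superset of models and is available as
  `threshold_mode=fixed` — it can admit exponentially many models on
  permissive data, hence not the default.
- **The null model's mass is not in the normalization constant**, so
  edge posteriors are conditional on at least one regulator being
  accepted. If nothing beats the null, all posteriors are 0.
- Duplicate subsets generated from different parents are evaluated
  once; re-evaluation would double-count mass.

Edge posterior j→i = (mass of accepted models containing j) / NC,
computed by a single batched log-sum-exp per regulator and clipped at
1 against rounding. Averaged strength β̄_ij is the posterior-weighted
mean of the maximum-likelihood coefficient, zero where j is absent;
|β̄_ij| therefore never exceeds the largest per-model coefficient.
The reported network keeps edges with posterior strictly above 0.75
(configurable); sign is "activator" for β̄ > 0, "inhibitor" for
β̄ < 0, "ambiguous" on exact cancellation.

## Evaluation

All ordered regulator–target pairs from the gold standard's
universes, self-pairs excluded, are ranked by score (unscored pairs
count as 0; direction matters: A→B and B→A are distinct). One PR
point per unique score groups ties. Area under the curve follows the
Davis–Goadrich interpolation as published: between consecutive
operating points, intermediate points are inserted at each unit
true-positive increment with false positives interpolated linearly
(placing them on the hyperbola precision traces between operating
points), and the area is the trapezoidal sum over the densified
sequence; the segment leaving the zero-recall origin contributes a
rectangle at its endpoint's precision, precision being undefined
before the first prediction. Perfect rankings score exactly 1. For a
random ranking the expected area is the class prevalence plus a
finite-list bias (≈ +0.019 at 15 positives among 90 pairs, computed
by Monte Carlo with an independent prefix-enumeration oracle);
published AUPRs computed under other tie/interpolation conventions
can differ by about this much.

## Network statistics

Computed on the thresholded network via networkx: out-degree ranks
transcriptional hubs; unnormalized directed betweenness (pure
shortest-path counts, edges unweighted — posteriors are not used as
weights) ranks junctions; PageRank (damping 0.85, uniform teleport,
dangling mass spread uniformly) ranks master regulators. For the
master-regulator ranking edges are **reversed** by default: plain
PageRank on regulator→target edges rewards being heavily targeted,
whereas reversing makes a regulator inherit the importance of the
hubs it controls. `--pagerank-direction forward` restores the plain
orientation.

## Synthetic data generator

The generator draws a random directed graph with
⌊density·n·(n−1)⌋ edges, coefficient magnitudes U(0.5, 1.5) with
Rademacher signs, self-decay U(0.2, 0.8), basal rates U(0, 0.5), and
iterates the same linear lagged dynamics the inference assumes, with
N(0, σ²) noise and U(0,1) initial states. The full system matrix is
rescaled to spectral radius 0.9 when it exceeds it, keeping
trajectories bounded — a simulator choice, not a claim about
biology. Defaults (10 genes, 5 series × 21 points, density 0.2,
σ = 0.05) mirror the small-benchmark setting of community challenges.
Gold standards exclude self-loops, matching benchmark conventions.

Because the generator uses the inference's own model class, recovery
tests certify the estimator, search and bookkeeping — not performance
on real transcriptomes, which are nonlinear, partially observed and
noisier. A fixed 5-gene, 6-edge fixture with switch-on/switch-off
style conditions (two series started low with basal drive, and high
without) provides a fast end-to-end pipeline check at the scale of
the classic in-vivo synthetic-network benchmark; it is generated
code, not measured data.

## Problem sizes and determinism

The test-suite and acceptance-script workloads are desk-scale by
design: 20-seed recovery batches at 10 genes, 10⁷-sample Monte-Carlo
marginal checks, 2000-replicate random-ranking baselines, brute-force
graph oracles on ≤ 10 nodes. Search and inference contain no
randomness: identical inputs, configuration and seeds give
byte-identical output files (fixed output ordering: descending
posterior, then lexicographic).

## Known limitations

- Linear, first-order, homoscedastic dynamics; no Hill-type
  saturation, no physical-time ODE integration.
- No missing-data model: NaNs are rejected at load.
- Time-lagged information only; instantaneous (same-time-point)
  regulation is invisible to the design.
- The binding-evidence prior requires externally prepared tier
  annotations; reconstructing consensus networks from raw ChIP-seq
  is out of scope.
- Edge posteriors are conditional on the search accepting at least
  one model; genes whose null model survives report empty rows.
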