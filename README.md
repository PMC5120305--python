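# bgrmi

Bayesian gene-regulation model inference: directed, signed,
probabilistic gene regulatory networks (GRNs) from time-course
expression data.

`bgrmi` is aimed at systems biologists with a time-resolved
transcriptomic experiment (multiple perturbation series, a handful to
a few hundred genes) who want, for every gene, not a single "best"
set of regulators but the posterior probability of every candidate
transcription factor (TF) → target interaction, together with a
signed strength (activator / inhibitor). Optional inputs sharpen the
inference: ChIP-seq-derived structure priors and TF–TF heterodimer
regulators. Benchmarking (precision–recall) and network-topology
analysis (hubs, junctions, master regulators) are built in.

## The model

Expression of gene *i* follows a discretized linear ODE: one sampling
step ahead,

    mRNA_i(t) = α_i + β_self·mRNA_i(t−Δt) + Σ_j β_ij·TF_j(t−Δt) + ε_i(t),
    ε_i(t) ~ N(0, σ²)

A *regulation model* M_k is a subset of candidate regulators (TF
monomers and heterodimers, a heterodimer's activity being the product
of its partners' mRNA levels). With a flat prior on α_i, Jeffreys
prior on σ², and a Zellner g-prior β ~ N(0, c·σ²(XᵀX)⁻¹) with the
Fernandez–Ley–Steel benchmark c = max(n, p²), the marginal likelihood
of M_k is closed-form:

    p(y | M_k) ∝ (1+c)^(−p/2) · [ c/(1+c)·SSE + 1/(1+c)·TSS ]^(−(n−1)/2)

where SSE is the least-squares residual of the model's fit and TSS
the centred total sum of squares. Combined with a structure prior —
the sparsity power law p(M_k) = L^−2.66, optionally multiplied by
per-TF binding-evidence Bernoulli terms P_ij = Q_ij·R from ChIP-seq
consensus networks — this yields an unnormalized posterior per model.

A greedy branch-and-bound search grows models one regulator at a
time, keeping those that beat the running posterior cutoff. Accepted
models are combined by Bayesian model averaging: the probability of
edge j→i is the normalized posterior mass of accepted models
containing j, and its strength β̄_ij is the posterior-weighted average
of the fitted coefficient (zero where j is absent). Edges with
posterior > 0.75 constitute the reported network; the sign of β̄_ij
labels activation vs inhibition.

## Worked example

Simulate a 10-gene network (density 0.2 → 18 true edges) under the
model's own dynamics, infer it back, evaluate, and rank hubs:

```sh
bgrmi simulate --genes 10 --series 5 --timepoints 21 --density 0.2 \
               --noise 0.05 --seed 1 --out-prefix sim
bgrmi infer --expression sim_series0.tsv --expression sim_series1.tsv \
            --expression sim_series2.tsv --expression sim_series3.tsv \
            --expression sim_series4.tsv --out edges.tsv
bgrmi evaluate --edges edges.tsv --gold sim_gold.tsv
bgrmi netstats --edges edges.tsv --metric outdegree
```

`edges.tsv` ranks every scored interaction:

```
regulator  target  posterior_probability  strength   sign
G1         G9      1.000000               0.567486   activator
G10        G8      1.000000               0.636470   activator
G2         G10     1.000000              -0.521085   inhibitor
```

and `evaluate` prints

```
AUPR            1.000000
positives       18
pairs           90
edges_above_0.75  18
```

— at this noise level the inferred ranking separates all 18 true
edges from the 72 decoys (area under the precision–recall curve 1.0),
and exactly the true edges survive the 0.75 posterior cutoff. Real
data are harder: nonlinear kinetics, unmeasured regulators and
measurement error all lower the AUPR.

DREAM4-dialect time-series files load directly with
`bgrmi infer --dream4 --expression file.tsv`; ChIP-seq tier
annotations become a prior matrix with `bgrmi priors`, passed to
`infer --prior-tsv`; heterodimers are declared with `--pairs`.

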