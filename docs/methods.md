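# Methods

## The model and the check

The Bayesian Skyline plot (BSP) assumes the sampled sequences come from one
panmictic Wright–Fisher population whose effective size Ne(t) changes
through time. Its key exposure is hidden population structure: a
structured sample produces gene trees whose branching-time profile no
single-population size trajectory can generate, and a naïve skyline read of
such data yields spurious size-change signals.

`skylinecheck` tests adequacy by posterior predictive simulation. The fitted
demography is summarized by two scalars extracted from the user's own
analysis artifacts:

* **θ̂** — the maximum-likelihood scaled population size under the
  constant-size coalescent, computed from the observed inter-coalescent
  intervals: with k lineages the interval τ_k is Exponential with rate
  C(k,2)/θ, giving the closed form θ̂ = Σ_k C(k,2) τ_k/(n−1). θ̂ inherits
  the tree's branch-length units (substitutions/site, years, …), and the
  identical rate parameterization drives the simulator, so estimator and
  null are mutually consistent by construction.
* **R** — the ancestral/current size ratio, drawn once per run by sampling
  Ne uniformly from the credible interval at the oldest skyline time
  (ancestral) and at the most recent time (current). The skyline posterior
  enters the test only through this ratio.

Null genealogies are simulated under the deterministic trajectory

    θ(t) = θ̂ · R^(t / t_ref),   t = age before present,

reaching the ancestral size at t_ref and held constant beyond it. Sampling
uses time rescaling with the closed-form inverse of the cumulative pair
intensity — piecewise over the exponential ramp and the constant tail — so
no numerical root finding is involved. Only node ages are generated: every
summary statistic is a function of ages alone, so no labeled topology is
needed (an optional random-join newick emitter exists for fixtures).

The default statistic is S = Σᵢ tᵢ/i with divergence times ranked oldest
(i = 1) to youngest. The oldest events dominate S, which targets exactly
the root-ward branch-length distortions structure induces. The two-tailed
Monte-Carlo p-value doubles the lesser tail count over the `n_sim = 100`
replicates; ties count on both sides (conservative) and the doubled value
is capped at 1. p = 0 is reported as computed, annotated "p < 1/n_sim",
with no pseudo-count correction.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| `n_sim` | 100 | replicates | standard for Monte-Carlo p-values at the 0.05 level; resolution 0.02 |
| `alpha` | 0.05 | — | conservative threshold balancing false negatives against false alarms |
| `statistic` | `cumulative` | tree time | most sensitive of the three to structure-induced distortion |
| `trajectory` | `exponential` | — | continuous size change; `instantaneous` switches to a step at t_ref |
| t_ref | oldest skyline time | tree time | the age at which the ancestral draw is defined; equals tree height for Tracer exports |
| `ratio_per_replicate` | off | — | one drawn R per run; enabling it propagates more posterior spread into the null |

Two choices deserve justification:

* **t_ref from the trace, not the tree.** The ancestral Ne is by definition
  the value at the oldest skyline time, so that age anchors the trajectory.
  For genuine Tracer exports the reconstruction spans the tree root and the
  two agree; when they differ (as in synthetic pairings), using tree height
  would silently rescale the posterior's time axis.
* **Capping θ(t) beyond t_ref.** An uncapped exponential with R > 1 decays
  the coalescence rate so fast that the total intensity is finite — a
  positive probability that lineages never coalesce. The cap keeps the tree
  distribution proper and mirrors the finite span of a skyline grid.

Uniform draws from the credible bounds are the minimal distributional
assumption given that only lower/upper are exported per row; the draw is
seed-controlled (one RNG stream per run, independently spawned streams per
replicate, so any replicate is reproducible in isolation).

## The validation study and its surrogate

`run_validation` reruns the evaluation design at desk scale: five
scenarios — constant size, tenfold expansion (R = 0.1), tenfold bottleneck
(R = 10), and two-population isolation with shallow (t_div = 2θ, i.e. 4N
generations) and deep (4θ = 8N generations) divergence — each at n = 10 and
n = 50 samples (isolation splits samples equally), 100 replicates per cell,
classified at α ∈ {0.01, 0.025, 0.05, 0.1}. One-population runs count as
model-conforming (a rejection is a false positive), two-population runs as
violations (a rejection is a true negative), pooled into a 2×2 table and
scored with the Matthews correlation coefficient, MCC =
(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)), taken as 0 when a marginal
is empty.

The MCMC inference stage is replaced by a **surrogate skyline posterior**: a
multiplicative 95% band (factor exp(±1.96·noise_cv), default noise_cv =
0.25) around the scenario's true size trajectory, with lognormal jitter on
the median, on a grid from the present to the scenario's reference age. For
the isolation scenarios the "true" trajectory is the census one: two demes
totalling 2θ merging into an ancestral deme of θ (step at t_div). With
noise_cv = 0 every row collapses onto the truth and the drawn ratio is the
scenario's R exactly.

What the surrogate deliberately does **not** emulate, and what that means
for interpreting results:

* no MCMC posterior: real credible bands are asymmetric, widen toward the
  root, and for structured data carry spurious size-change signal; the
  surrogate's band is centered on truth with constant relative width;
* no sequence simulation or tree re-estimation: the true genealogy is fed
  directly as the MCC-tree input, removing phylogenetic error entirely.

Passing the desk-scale study therefore demonstrates the internal
consistency of the machinery (estimation, simulation, p-value mechanics,
classification bookkeeping), not the field performance of the full
sequence→MCMC→check pipeline.

## Behavior under the study conditions

Two properties of the plug-in design show up clearly at desk scale and are
worth knowing before reading any report:

* **Conservatism under the null.** θ̂ is refit from the same tree whose
  statistic is tested, so the empirical tree is never unusual relative to
  nulls built around it (in the extreme n = 2 case the statistic *is* θ̂
  and p ≈ 0.74 always). Measured over 1,000 runs at n = 10 with the default
  surrogate noise, rejection rates are ≈ 0.01/0.026/0.036 at nominal
  0.01/0.05/0.1: the test under-rejects, it does not over-reject. Reported
  p-values are honest but conservative; the full pipeline's additional
  inference noise moves rates toward nominal.
* **Sensitivity of false positives to strong one-population size change.**
  θ̂ is a time-average, but the null plugs it in as the *current* size of
  the R-fold trajectory. For the study's tenfold magnitudes this mismatch
  inflates false positives (most visibly the bottleneck cells), which
  drags the pooled desk-scale MCC below zero and inverts its trend across
  α. This is a property of the plug-in construction itself, not of the
  surrogate; with mild size changes (R within a few fold) the effect is
  negligible.

Power against structure rises with divergence depth and sample size
(deep ≥ shallow, n = 50 ≥ n = 10 in rejection rate), the qualitative
pattern expected of the test, though absolute desk-scale power is modest
because a truth-centered surrogate contains none of the spurious
skyline signal that structured data induce in real inference.

## Numerical notes and degenerate inputs

* Ultrametricity is checked to a relative tolerance (default 1e-6 × height,
  configurable; `coerce` waives it) because MCC trees carry float jitter;
  node ages are clipped at 0 after subtraction from the height.
* Tied node ages are legal and yield zero-length intervals; a tree of zero
  height raises a degenerate-tree error (θ̂ undefined).
* Polytomies are rejected with a hint to resolve them externally; the
  lineage-count bookkeeping assumes strictly binary coalescences.
* Skyline tables are matched on case-insensitive column prefixes (so
  Tracer's "Upper 95% HPD" works), rows are re-sorted by time, and
  lower ≤ median ≤ upper and positivity are enforced on parse.
* The statistic contrast of consecutive interval lengths needs at least two
  intervals and is undefined (error) on 2-tip trees; signed and all-pairs
  variants are provided for sensitivity analysis.
* All randomness flows from one integer seed through `numpy` SeedSequence
  spawning; identical seed and inputs give bit-identical results.

## Known limitations

* Single locus, single test: no multi-locus aggregation or multiple-testing
  correction across datasets.
* The ratio reduces the whole skyline to its endpoints; mid-trajectory
  misfit (e.g. a transient crash) is invisible to the null's monotone
  trajectory family.
* Newick only (one tree per file); nexus/BEAST XML are out of scope, as are
  recombination, migration and sequence-level simulation.
* The validation surrogate bounds what the study can claim about real
  pipelines (see above); treat desk-scale MCCs as internal diagnostics, not
  field performance estimates.
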