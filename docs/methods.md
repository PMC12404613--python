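# Methods

This note documents the models, conventions, numerical choices, and
deliberate simplifications behind the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Neutrality laws and residuals

Fitness `W` is the growth rate of a mutant relative to wild type (WT = 1).
For single-mutant fitnesses `W_x`, `W_y` the implemented null models are

| law | prediction `W_xy` | reading |
|---|---|---|
| product | `W_x · W_y` | a mutation's absolute effect scales with the background |
| additive | `W_x + W_y − 1` | fitness defects add independently |
| minimum | `min(W_x, W_y)` | the worst mutation is rate limiting |
| scott_hwa | `1/(1/W_x + 1/W_y − 1)` | exact law of the optimal two-sector model |

The epistasis residual is **observed − predicted** (`w_xy − law(w_x, w_y)`),
chosen so that a law predicting fitnesses that are too high produces
negative residuals. Residuals are summarised in 10 equal-width bins of
`max(W_x, W_y)` on [0.5, 1.0]; bins are half-open `[lo, hi)` with the last
bin closed so `max_single = 1.0` is counted. Percentiles use linear
interpolation between order statistics (numpy's default); the convention
is fixed here because it affects reported medians at the third decimal.
A reference fitness of 0.72 falls in the bin [0.70, 0.75).

Because the Product law commutes with power transforms
(`(W_x W_y)^p = W_x^p W_y^p`), fitnesses defined from colony expansion
rates (proportional to the square root of the single-cell exponential
rate) and from liquid-culture exponential rates are equivalent for it. No
dedicated operation implements this; it is asserted as a property test
(`p = 1/2`).

## SGA preprocessing

Input tables are tab-separated with one row per query × array cross;
gene identifiers are the strain IDs up to the first underscore (regex
configurable). Two filters are applied, in either order (they commute and
are idempotent; the preprocessing report reconciles exactly):

1. **Deleterious filter** — drop records with a *single*-mutant fitness
   above 1. Double-mutant fitnesses above 1 are retained by default: the
   filter restricts the set of *mutations* to deleterious ones, and the
   double-mutant value is the quantity under test. A `strict` flag also
   drops `w_xy > 1` for sensitivity analyses.
2. **Additive-domain filter** — drop records with `W_x + W_y < 1`
   (strict; the boundary `= 1`, where the Additive prediction is exactly
   0, is retained), so all laws are evaluated on one common record set.

Duplicate gene pairs are retained as independent records; missing values
are dropped, never imputed.

## Process-pair analysis

Annotations map genes to (possibly several) biological processes, read
from a two-column TSV or a GAF 2.x file (evidence-code filtering off by
default). Processes need at least 50 annotated genes among the dataset's
genes (counting unique genes, regardless of query/array role). Pairs of
distinct processes are kept only when their dataset-restricted gene sets
are disjoint. Each pair's residual profile uses records with one gene in
each process (either role); intra- vs inter-process comparison classifies
a record as *intra* when its genes share at least one selected process,
excludes records with an unannotated gene, and reports two-sided tail
fractions of the residual at a configurable threshold (default 0.1). No
GO-graph propagation or enrichment statistics are performed.

## The two-sector model

Growth is the balanced flux of a translational sector (proteome fraction
`φ_t`, efficiency `κ_t`) and a metabolic sector (`φ_n`, `κ_n`) with a
reserved housekeeping fraction `φ_o`:

    λ = κ_t φ_t = κ_n φ_n,   φ_t + φ_n + φ_o = 1
    ⇒ λ* = (1 − φ_o) / (1/κ_t + 1/κ_n).

A mutation rescales one parameter (`α' = θα`, θ ~ U(0,1] for deleterious
scans; θ = 0 exactly is excluded to keep fitness ratios defined). For one
mutation to each κ the double-mutant fitness has the exact closed form
`W_xy = 1/(1/W_x + 1/W_y − 1)`. In scans the model fitness is computed by
*numerical* maximisation of `min(κ_t φ, κ_n (1 − φ_o − φ))` — a
fixed-iteration (90) golden-section search on the concave piecewise-linear
objective, accurate to machine precision — so the closed form is checked
against a genuine optimisation rather than against itself. `φ_o` cancels
from every fitness ratio of κ-mutations, and a mutation to `φ_o` combines
exactly multiplicatively with a κ-mutation; the default `φ_o = 0`,
`κ_t = κ_n = 1` therefore loses no generality for fitness statistics.

Freezing the allocation at the WT optimum removes the re-allocation
feedback and collapses the double mutant onto `min(W_x, W_y)` exactly.
For beneficial mutations (θ ~ U(1, θ_max), default θ_max = 2,
configurable) the model fitness exceeds the Product, Additive, and
Minimum predictions, and the closed form's denominator vanishes at
`W_x = W_y = 2` — the divergence point recomputed by root-finding
(Brent) in the acceptance script.

## The mechanistic ODE model

A fixed-mass (`M`) cell with 14 state variables: internal nutrient `s_i`,
energy `a`, free ribosomes `r`, and free mRNA `m_x`, ribosome–mRNA
complexes `c_x`, proteins `p_x` for four classes x ∈ {r, t, m, q}
(ribosomal, transporter, metabolic enzyme, housekeeping). Kinetics:

* import `p_t · v_t · s / (K_t + s)`; catabolism
  `p_m · v_m · s_i / (K_m + s_i)` yielding `n_s` energy units per
  nutrient;
* transcription `ω_x = w_x · a / (θ + a)` with threshold `θ_r` for the
  ribosomal class and a shared `θ_x` for the three others
  (`γ ≡ 1/θ_x`); the q class carries an autoinhibition factor
  `1/(1 + (p_q/K_q)^{h_q})`;
* mass-action ribosome–mRNA binding (`k_b`, `k_u`); free-mRNA
  degradation `d_m`;
* translation at `g(a) = g_max · a / (K_p + a)` aa/min per complex
  (protein x costs `n_x` residues and energy units), each completed round
  releasing ribosome and mRNA;
* growth `λ = g(a) · Σ c_x / M`, diluting every species.

Total protein mass relaxes to `M` exactly (`dM_tot/dt = λ(M − M_tot)`),
which the tests use as a conservation check together with the
steady-state energy balance `n_s v_cat = g(a) Σc + λa`. Parameter values
ship as a versioned YAML asset (`neutrality/data/weisse_wt.yaml`, units
documented inline) and follow the published defaults of this model
family; all scan results are stated relative to that asset. The ribosomal
transcription threshold is kept distinct from the shared non-ribosomal
one because collapsing them overdrives ribosomal mRNA production by two
orders of magnitude, inverts the sign of the growth response to `w_r`,
and cuts wild-type growth ~9-fold — a qualitatively different and
non-physiological model.

### Steady states

Two independent routes, cross-checked in the tests to < 1e-6 relative
growth rate:

* **Integration** — LSODA from a standard non-zero seed state;
  convergence requires the relative change of λ across the last 10% of
  the horizon (default 1e4 min) to fall below 1e-8, doubling the horizon
  up to 3 times otherwise.
* **Reduced root solve** — at steady state the mRNA/complex/protein
  balances are linear given `(a, r, λ, s_i, p_q)`:
  `c_x = k_b r ω_x / ((λ + d_m) d_x + λ k_b r)` with
  `d_x = k_u + λ + g(a)/n_x`, `m_x = d_x c_x / (k_b r)`,
  `p_x = g(a) c_x / (n_x λ)`; five residual equations remain (growth
  definition, free-ribosome balance, q self-consistency, energy balance,
  nutrient balance), solved by Powell's hybrid method in log variables.
  Every reduced solution is verified against the *full* 14-equation
  system (scaled derivative < 1e-6) before being accepted.

Scans warm-start the root solve from the wild-type (or single-mutant)
solution; if that fails — severe mutations can sit far outside the
warm-start basin, with growth rates orders of magnitude below wild type —
a log-linear parameter-space continuation walks from the reference to the
target with adaptive step halving (minimum step 1/64), and integration is
the last resort. Samples that still fail are dropped and counted
(`n_failed`); at the default conditions none do.

### Mutational scans

Nine parameters have an interpretable, verifiably deleterious
multiplicative direction: rates and efficiencies shrink (`θ·value`),
Michaelis constants and the mRNA degradation rate grow (`value/θ`).
Process grouping:

| process | parameters |
|---|---|
| metabolism (uptake chain) | `v_t, K_t, v_m, K_m` |
| nutrient efficiency | `n_s` |
| transcription | `w_e, d_m` |
| translation | `g_max, K_p` |

giving 28 cross-process pairs. The choices that need justification:

* `w_r` and `w_q` are excluded because *reducing* either increases the
  wild-type growth rate (verified numerically): the wild-type
  transcription allocation is not growth-optimal, so these parameters
  have no deleterious multiplicative direction in [0, 1].
* The import and catabolism parameters form a single process: both
  protein classes are transcribed at the same rate `w_e`, so the model
  cannot re-allocate between them, and serial-chain pairs such as
  `(v_t, v_m)` follow an exact Minimum law — they are not independent
  processes in this model and are excluded (grayed out) like any
  same-process pair. Metabolism also has ~9-fold slack over import at
  the default parameters, so `v_m`/`K_m` mutations are nearly neutral
  until θ is extreme.

Each pair scan draws θ ~ U(0,1] independently for the two parameters,
computes the two single and the double steady states, discards and counts
mutants that (contrary to design) increased growth, and reports the mean
absolute deviation of `w_xy` from each law (the signed mean is kept
alongside; "deviation" is absolute by default). Translation-involving
pairs track the two-sector closed form — a translation mutation rescales
the global translation budget, the same role as a sector efficiency —
while the remaining pairs track the Product law. The comparison is made
at the subset level (mean over translation-involving pairs vs mean over
the rest): individual near-degenerate pairs (e.g. those involving `K_m`,
where the single-mutant fitness is ≈ 1 for almost all θ) make all laws
coincide and carry no signal either way.

### The γ sweep

`γ = 1/θ_x` controls how nonlinearly (non-ribosomal) transcription
responds to energy. The sweep sets `θ_x = 1/γ`, recomputes the wild type
per γ (fitnesses are always relative to the matched wild type), and
reuses the same mutation draws across γ values (common random numbers),
so the between-γ comparison carries no sampling noise. For the metabolic
pair `(v_t, n_s)` the median |Product residual| is flat while
transcription is energy-saturated and decays to ~1e-5 once
`θ_x` exceeds the steady-state energy scale (a* ≈ 10 energy units at the
default parameters); the default sweep values (0.1, 0.03, 0.01, 0.003)
span that crossover, which is the regime where the transcription
nonlinearity — rather than the other Michaelis–Menten steps — governs
the deviation.

## Synthetic data

The generator emulates the statistical structure the residual analysis
assumes: single-mutant fitnesses i.i.d. on (0, 1] from a mixture of a
near-1 component (weight 0.35; `1 − |N(0, 0.02)|`) and a deleterious tail
(Beta(1.4, 1.1) stretched over [0.35, 1]) — most mutations mild, a broad
deleterious tail covering the binned range; double-mutant fitnesses from
a chosen law plus additive Gaussian noise truncated at 0 (noise is
additive because the residual is defined additively; a multiplicative
mode exists behind a flag); uniformly sampled gene pairs; and chain-
structured process annotations (consecutive processes share
`overlap_fraction · genes_per_process` genes) with optional extra intra-
process noise. It does **not** emulate colony geometry, plate or batch
effects, the real screens' shared-query correlation structure, or
fitness-dependent measurement error — so passing recovery tests show the
*pipeline* is unbiased and discriminating under the stated noise model,
not that the real screens are.

One statistical caveat is handled explicitly: bins of `max(W_x, W_y)`
near 0.5 require both singles near 0.5 and (after the additive-domain
filter) hold only a thin slice of records, so their medians carry
sampling noise of several times 1e-3 even at 50 000 pairs. Recovery
checks therefore hold each bin median to
`max(0.003, 3 standard errors of the median)` (`SE ≈ 1.2533 σ/√n`),
which reduces to the fixed ±0.003 exactly where the bin is populated
enough for that figure to be meaningful (n ≥ 2500 at σ = 0.05).

## Problem sizes and runtime choices

Test-suite runs use the sizes the checks need, not more: law-recovery at
100 replicates × 50 000 pairs per generating law; the mechanistic scan at
200 mutants per pair (28 pairs) with the γ sweep at 500 mutants per γ;
module-level scans at 20–80 mutants per pair. The two-sector analyses are
vectorised and effectively free. A full pipeline run on the bundled
synthetic configurations completes in well under five minutes on one CPU.

## Known limitations

* The mechanistic model's published parameter point is not
  growth-optimal in every coordinate (see `w_r` above); conclusions about
  "deleterious" directions are statements about this parameter point.
* The loader for released screen data is format-faithful but the
  published headline residual numbers are not recomputed here, since the
  deposited dataset is not bundled; the pipeline reproduces the sign
  pattern and bin conventions on synthetic data instead.
* Interaction-profile correlation clustering and per-interaction
  significance calls are out of scope.
* The mechanistic model is deterministic; stochastic gene expression,
  cell size, and division are not modelled.
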