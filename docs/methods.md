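# Methods

## Model

A dose-response curve is modelled as a product of independent Hill
phases on the normalized response scale (baseline 1, complete
inhibition 0):

    E(C) = E0 · Π_{i=1..n} [ E∞_i + (1 − E∞_i) / (1 + (C/EC50_i)^{H_i}) ]

Each factor describes one dose-dependent process; the product is the
Bliss-independence composition of processes that converge independently
on the same phenotype. The formulation assumes the zero-dose response
is unity, which is why all input response scales (percent viability,
inhibition fractions, …) are converted to the canonical 1→0 scale on
read. `E0` (`baseline_scale`) is an optional global factor absorbing
modest control-normalization error; it is fixed at 1 unless explicitly
freed, in which case it is bounded to [0.5, 2] — it corrects a poorly
estimated control, it does not rescale arbitrary data. At `C = 0`
every factor is evaluated by its exact limit (value 1), avoiding the
`0^H` ambiguity.

A phase with `E∞ = 1` is an identity factor: it changes nothing
anywhere, and is how the simpler candidate configurations embed in the
richest one. Phases are stored sorted by ascending EC50 (stimulatory
first on ties) so "the first inhibitory phase" is well defined in
reports. Model evaluation supports any number of phases (the
five-phase reference shape exercises this); the *selection* search is
restricted to the four configurations below, because each extra phase
costs three parameters and real assay noise rarely supports more.

## Candidate configurations and selection

Four candidates are fitted, in this order:

| label          | roles                                   | free parameters |
|----------------|-----------------------------------------|-----------------|
| HILL_1I        | inhibitory                              | 3               |
| BIPHASIC_2I    | inhibitory, inhibitory                  | 6               |
| BIPHASIC_1S1I  | stimulatory, inhibitory                 | 6               |
| TRIPHASIC_1S2I | stimulatory, inhibitory, inhibitory     | 9               |

(+1 each when the baseline factor is freed.) Candidates are ranked by
BIC (AIC available), lowest proposed; exact ties break toward fewer
free parameters, then toward the earlier candidate. Each richer
candidate is warm-started from every fitted simpler candidate with its
surplus phases parked numerically at the identity, in addition to its
own fresh starts. This warm start is what makes the nesting property
(richer candidates never fit materially worse) hold in practice on
multimodal objective surfaces. A candidate that converges to an
effectively simpler model — a phase within 1e-3 of the identity, an
EC50 more than 3 decades outside the tested range, or a fitted curve
within 1e-3 of a simpler candidate's everywhere on the tested grid
(e.g. a mutually cancelling stimulatory/inhibitory pair) — is kept in
the ranking but flagged `effectively_simpler`.

## Objective and weights

    F = Σ_j Σ_i [E_exp,i(c_j) − E(c_j)]² / w_j²

summed over non-missing cells only (missing values are skipped, never
imputed). With `sd` weighting, `w_j = σ_j`, the per-concentration
dispersion; with `unit` weighting `w_j = 1`.

Per-concentration σ estimation: concentrations with ≥ 2 replicates get
their sample sd; but a triplicate sd has only 2 degrees of freedom and
the expectation of its inverse square does not exist, so raw
inverse-variance weights are heavy-tailed and destabilize model
comparison. The estimates are therefore moderated in empirical-Bayes
fashion: each variance is shrunk toward the dof-weighted pooled
variance with prior dof ν₀ = 4 (`σ̃_j² = (ν_j s_j² + ν₀ s₀²)/(ν_j + ν₀)`,
the same device as moderated-statistics frameworks in genomics).
Homoscedastic data pass through unchanged. Rows without a usable sd get
the pooled value; if no row has one, weights are unity and the dataset
is flagged as better served by unit weighting.

## Scores

Under sd weighting, F is built from σ-standardized residuals and is the
−2 log-likelihood core of the Gaussian model, so (constants dropped)

    AIC = F + 2k,   BIC = F + k ln N,

with `k` the free-parameter count and `N` the number of non-missing
observations. Under unit weighting (including the automatic fallback on
data without replicate scatter) the noise variance is unknown; the
variance-profiled Gaussian likelihood gives the standard least-squares
forms

    AIC = N ln(RSS/N) + 2k,   BIC = N ln(RSS/N) + k ln N,

with RSS/N floored at 1e-12 (an effect-scale sd of 1e-6, far below any
assay's precision) so that candidates which interpolate the data
exactly tie on the fit term and the parameter penalty decides — this
is what preserves the conservative simpler-model preference on
noiseless data. Goodness of fit is the upper-tail χ² probability of F
at `N − k` dof, reported only under sd weighting (where F is
calibrated) and only when dof > 0.

## Optimization

All optimizers minimize the same F through the same transformed
parameter vector: per phase `(log10 EC50, ln H, u)` with the asymptote
mapped through a sigmoid into [0, 1) for inhibitory phases and
(1, E∞_max] (default E∞_max = 5) for stimulatory ones; a trailing
sigmoid coordinate maps to the baseline factor when free. Positivity
therefore needs no hard constraints, and every iterate stays in the
interpretable regime.

* `trust_region` (default): trust-region-reflective bounded least
  squares on the √weight-scaled residual vector, whose implicit
  objective equals F exactly. Bounds: log10 EC50 within the tested
  range ±6 decades, H in [0.05, 20], sigmoid coordinates in ±14.
* `simplex`: Nelder-Mead on the same vector.
* `simplex_constrained`: Nelder-Mead plus a soft separation penalty,
  `10⁶ · Σ max(0, δ − Δlog10 EC50)²` over consecutive phase pairs with
  δ = 0.5 decades by default — an operational form of "no overlap of
  processes in concentration space", scaled to dominate F near
  violation.

Initialization is a deterministic multi-start scheme (default 10
starts; screens in this repository use 4–6, which warm starts make
sufficient): log-EC50s at quantiles of the tested log-range, ordered
and separated; H at 1; inhibitory asymptotes from the mean effect at
the top concentration (split multiplicatively across inhibitory
phases); stimulatory asymptotes from the maximum mean effect (at least
1.2); seeded Gaussian jitter across the remaining starts, clipped back
into the tested range and re-ordered. Convergence tolerances default to
1e-8 on F and on parameters, 2000 iterations per start. The best start
by final F wins; results are bit-reproducible given (data, settings,
seed).

## Effective concentrations and AUC

ECx on a multiphasic curve is ambiguous (absolute vs span-relative
level; which crossing). The package solves
`E(c) = b − level·(b − E_floor)` where `b` is the baseline factor and
`E_floor` the model value at the search window's upper edge — a
span-relative definition that degrades exactly to the textbook Hill
ECx for monophasic models (the window must extend far enough past the
transition that `E_floor ≈ E∞`; the default window spans the phase
EC50s ±6 decades). All crossings found by a 1000-point log-grid sign
scan refined by bisection (relative tolerance 1e-9) are returned in
ascending order; the smallest is the primary ECx; none is an explicit
empty result with a warning, never a silent extrapolation. AUC is the
2001-point composite-trapezoid integral of E over log10 C, optionally
normalized by the interval width to a mean-effect scale.

## Synthetic data

The generator exists so every pipeline stage is testable without
external data. It draws effects as `E(c_j) + ε`, ε Gaussian with a
per-concentration sd σ (default 0.05 on the normalized scale, a typical
well-run viability assay), truncated at 0 from below since a viability
readout cannot be negative — which slightly biases noise near complete
inhibition; recovery tolerances account for it. Default design: 11
concentrations in half-decade steps over 5 decades, 3 replicates.

Screens mix the four classes in chosen proportions (multinomial draw,
or exact largest-remainder counts). Per-curve parameters: log10 EC50
uniform in the interior of the tested range (0.5-decade margin, so
every transition is observable) with ≥ 1.5 decades between consecutive
phases; H uniform in [0.5, 4]; stimulatory E∞ in [1.2, 1.6]; terminal
inhibitory E∞ in [0, 0.4]; intermediate inhibitory E∞ in [0.35, 0.65]
so the plateau between inhibitory transitions actually shows (with both
asymptotes small the product collapses before the second phase engages
and the classes are not distinguishable even in principle).

What passing on such data does and does not show: the generator matches
the noise model the objective assumes (independent Gaussian,
per-concentration σ), has no plate effects, no outliers, no
concentration error, and phases separated by construction. Recovery and
classification results here are therefore an upper bound on real-assay
performance; the ~95% class recovery measured on the default screen
should be read as "the procedure works when its assumptions hold", not
as a field error rate.

## Problem sizes and determinism

The recovery studies use 50 curves per scenario (triplicates; 9
concentrations over 4 decades for the monophasic study, the default
11-point half-decade design for the biphasic one, whose two transitions
need the finer sampling) and the classification study 200 curves (50
per class),
sizes at which medians and per-class accuracies are stable to a few
percent; all randomness flows from explicit integer seeds, and batch
runs derive one seed per curve id so reruns are byte-identical.

## Known limitations

* The selection search covers the four configurations only; curves with
  more phases (or two stimulatory phases) are classified to the nearest
  searched configuration.
* Asymmetric (5PL-style) phases are not modelled.
* No parameter uncertainty quantification (no bootstrap/profile CIs).
* GOF requires honest replicate-based σ; under unit weighting it is
  deliberately absent.
* The span-relative ECx depends on the search window's upper edge for
  curves that have not plateaued inside it.
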