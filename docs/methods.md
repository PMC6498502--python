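# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `mselink`, in the package's own words.

## Estimand and data model

The estimand is the size N of a closed cohort of deaths over a fixed
window, of which only those appearing on at least one of three source
lists are observed. The data reduce to the seven observable
capture-history counts x_ijk (i, j, k ∈ {0,1}, not all zero); x_000 is
unobserved. Cell counts are modelled as independent Poisson with

    log m_ijk = b0 + bi·i + bj·j + bk·k + Σ pairwise interactions,

where an interaction term (say ij) allows appearing on list i to change
the odds of appearing on list j. With three lists the three-way term has
no observable degrees of freedom, so the model family is exactly the
2³ = 8 subsets of {ij, ik, jk}: residual df 3 (independence) down to 0
(saturated). Because the (0,0,0) design row carries only the intercept,
every model predicts the unseen cell as m_000 = exp(b0), equal to the
fitted-cell cross-ratio m_111 m_100 m_010 m_001 / (m_110 m_101 m_011).

Key assumptions inherited from the method: the cohort is closed over the
window; linkage is correct (a false non-match inflates, a false match
deflates the estimate); capture is homogeneous across individuals within
a list; and list dependence is at most pairwise. The eight-model average
relaxes the independence assumption but cannot detect three-way
dependence, which is unidentifiable here.

## Fitting

"Bayesian with uninformative priors" is operationalized as: per model,
the posterior mode under flat priors is the Poisson MLE, obtained by
Newton iterations with step halving (analytic gradient and Hessian of the
log-likelihood), converging when the largest fitted-cell change falls
below 1e-10, capped at 500 iterations. Starting values come from a least
squares fit to log(x + 0.5). The deviance is G² = 2 Σ x log(x/m) with
0·log 0 = 0. Tests cross-check the fitter against an IRLS GLM
(statsmodels) and against direct Nelder–Mead maximization of an
independently coded likelihood.

## Model comparison and averaging

BIC is computed on the deviance scale, BIC = G² − df·ln(n_obs) with
n_obs the total listed count, so the saturated model sits at 0 by
construction and pairwise BIC differences are standard. Posterior model
probabilities are Schwarz weights Pr_i ∝ exp(−BIC_i/2) under a uniform
model prior, computed with a max-shift (hence invariant to adding a
constant to all BICs). The model-averaged unseen count is Σ m_000,i Pr_i;
the reporting layer rounds point estimates and sensitivities to the
nearest integer (halves away from zero), keeping unrounded values on the
result objects. This BIC-weight reading reproduces, to three decimals,
all eight published posterior probabilities of the demonstrations
analysis from its published BIC column, which is why no MCMC machinery
was introduced.

## Interval estimation

Per-model intervals use the profile likelihood of the unobserved *count*:
for integer g on a grid from 0, the table is completed with x_000 = g,
the model refitted on all eight cells, and the full log-likelihood —
including the −log g! term, which is what makes the profile carry the
unseen count's own sampling variability in addition to estimation noise —
recorded. The normalized profile is treated as a distribution over g and
its 2.5th/97.5th percentiles (linear interpolation on the cumulative sum
between integers) give the 95% interval. A deviance-cutoff alternative
(χ²₁-based) is exposed as `method="deviance"`. The grid ceiling starts at
max(50, 20 × point estimate) and doubles while the top grid point retains
relative likelihood above 1e-8.

The model-averaged interval is taken from the Pr-weighted mixture of the
per-model normalized profiles, shifted by n_obs for the N scale. The
source analysis does not state how its averaged interval was formed; this
mixture is this package's choice (it is the model-averaged posterior of
the unseen count under the profile-as-posterior reading) and exact
reproduction of the published averaged interval is not claimed.

### Boundary tables

If an observed cell in the denominator of the cross-ratio is zero, the
saturated estimate is infinite and several profiles decay like g^(−c)
with c ≤ 1 — too slowly to normalize. `profile_interval` widens its grid
and then raises; the averaging pipeline instead truncates such a model's
profile at `max_ceiling` (default 4000) with a `BoundaryWarning`, since
those models typically carry negligible weight and aborting the whole
average would discard the informative models. An optional continuity
correction (+0.5 to every cell; `continuity=True` or `"auto"`, which
applies it only to tables with an empty observed cell) keeps point
estimates finite; it is off by default because the original analysis
applies none.

## Record linkage

Records merge if and only if their normalized names match exactly
(casefold, diacritics stripped, punctuation removed, whitespace
collapsed) and no *known* auxiliary field conflicts (kind, gender, date,
place, cause; wound site only when both records are gunshot deaths).
Unknown never conflicts with known; merging is transitive via connected
components; intra-list duplicates collapse in the same pass and are
logged. Differing known dates — even by one day — are treated as a
conflict; the original compilers reconciled such cases manually and no
claim is made of matching their judgment. An edit-distance-1 fuzzy match
exists as an opt-in policy knob and is off by default, since the source
material reported no ambiguous near-matches. Determinism and order
invariance are obtained by canonically sorting records before component
formation and field resolution (majority value, ties broken
lexicographically).

Exclusion rules mirror the analysis cohort: records whose role matches
security-force patterns are removed, as are records identifiable neither
by name nor by at least two of {date, place, cause}. Period restriction
is half-open [start, end); persons with unknown dates are excluded from
period tables and logged rather than imputed.

## Synthetic cohorts

The generator draws each individual's capture history from the
multinomial over the eight cells with

    p(h) ∝ Π_l (p_l/(1−p_l))^{h_l} · exp(Σ_{l<m} θ_lm h_l h_m),

so θ = 0 gives independent lists with marginal capture probabilities
exactly `capture_probs`, and θ_lm is the (conditional) log odds-ratio
between lists l and m — the natural conjugate of the fitted family. No
three-way dependence is generated because the fitted family excludes it.
Defaults mirror the demonstrations cohort: a true toll of 75 with
per-list completeness (0.73, 0.64, 0.60), ~96% male, ~14% minors, cause
mix ~74% gunshot among known causes, dates uniform over
2018-12-19…2019-02-28. Attributes are drawn independently of capture, so
the generator does not emulate capture heterogeneity (e.g. deaths in
smaller towns being harder to list), behavioural responses, or
transliteration ambiguity; name noise is limited to benign case,
whitespace and punctuation variants that normalization absorbs. Passing
tests therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to violations real lists may exhibit.

## Verification scales

The test suite checks, among other properties: fitter agreement with
brute-force likelihood maximization on 50 random small tables (relative
cell error ≤ 1e-4) and with a closed-form independence pattern (≤ 1e-8);
saturated-model exactness; label-permutation invariance of the averaged
estimate; no-interaction bias and 93–97% profile-interval coverage over
500 multinomial replicates at N = 100, p = (0.7, 0.6, 0.6); and full
end-to-end recovery (simulate → emit → link → tabulate → average) with
mean relative bias ≤ 5% and 93–97% coverage over 300 seeds at the same
conditions. These sizes keep the default suite in a few minutes on one
CPU while leaving Monte-Carlo error small relative to the asserted bands.

## Known limitations

- No probabilistic (Fellegi–Sunter) linkage, no Arabic-script handling —
  names are assumed pre-transliterated.
- No uncertainty propagation across spliced periods: the spliced totals
  are point arithmetic, as in the source analysis, and the two-list
  period's interval is deliberately not combined into them.
- Two-list Petersen estimation is undefined without overlap; Chapman's
  correction is offered but never silently substituted.
- Sensitivity intervals are derived by inverting the N interval, so they
  inherit whatever coverage the N interval has.
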