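# Methods

This note documents the statistical model behind the package, the
defaults it ships with, and the choices made where the design was
genuinely open.

## Burden model

For one disease, the burden of an incident case is

- **YLIW** (years lived with impaired welfare): the sum over all sequela
  items of `P_i × D_i × IWW_i`, where `P_i` is the probability that a
  case develops welfare impediment *i*, `D_i` its mean duration in
  years, and `IWW_i` the impediment's severity weight on [0, 1]. The
  death impediment never contributes to this sum.
- **YLL** (years of life lost): the residual life expectancy at the age
  of premature death (age at diagnosis + mean survival), read from a
  life table by linear interpolation and multiplied by the case
  fatality carried on the death sequela item. Scaling by case fatality
  is required for internal consistency: diseases that kill only a few
  percent of cases (e.g. thoracolumbar disc disease) print sub-year YLL
  values that a bare residual-expectancy reading cannot produce.
- **WALY = YLIW + YLL**, enforced per Monte-Carlo draw, so the identity
  holds exactly in every draw and in expectation.
- **Weighted YLL = YLL × IWW(death)** treats death as a welfare state
  rather than a total loss; weighted WALY = YLIW + weighted YLL, and is
  never larger than the unweighted WALY.

Life-table policy: ages beyond the last tabulated row clamp to the final
expectancy (with a logged warning — this affects long-survival draws);
ages below the first row are an error, since early-life burden is out of
scope. Durations are *not* capped at the residual lifespan: chronic
diseases are modelled with lifetime-scale durations, and capping is left
to sensitivity analyses.

Uncertainty is propagated with Monte Carlo (default 100 000 draws).
Epidemiological inputs carry declarative uncertainty specs — `point`,
`uniform(low, high)`, `normal(mean, sd)`, `lognormal` (median plus a
range interpreted as a central-95% interval on the log scale) and
`beta(mean, n)` — validated before any sampling. IWWs are drawn from
their logit-normal distributions. Each quantity is summarised by its
mean and the 2.5th/97.5th percentiles (95% UI).

## Weight elicitation

1. **Paired comparisons → probit scale.** Each answered question "which
   of these two dogs has better welfare?" becomes a contrast row: +1 for
   the first impediment, −1 for the second, 0 elsewhere, outcome 1 if
   the first was chosen. The contrast matrix is negated before fitting
   so that larger coefficients mean worse welfare. One reference
   impediment is fixed at 0; the comparison graph must be connected.

   The fit is penalized maximum likelihood: a Newton solver on the
   stable `log Φ` likelihood plus a small ridge on all pairwise
   coefficient differences (`ridge_alpha`, default 0.01, spread over the
   pairs). Because the penalty depends only on severity *contrasts*, the
   fitted contrasts — and hence the final weights — are invariant to the
   reference choice. The penalty also keeps coefficients finite under
   quasi-separation (an impediment that wins or loses almost every
   comparison), which occurs regularly at realistic survey sizes.
   Setting `ridge_alpha=0` gives pure ML, and genuinely separated data
   then raise an error that recommends more data or penalization.
   Respondents are pooled (no clustering), so the standard errors are
   model-based; no intercept is included, as an intercept would model a
   first-position presentation bias.

2. **Anchor values.** Five impediments chosen to span mild-to-severe
   welfare compromise are valued directly: VAS weights are the mean of
   `1 − placement/100`, TTO weights the mean of `1 − traded years/10`
   (choosing not to trade ⇒ weight 0). Infeasible responses (out of
   range, or flagged at capture, e.g. a placement contradicting the
   respondent's own severity ranking) are removed first, with an
   exclusion report.

3. **Anchoring map.** Anchor weights are clipped into
   [1e−4, 1 − 1e−4] and logit-transformed; a locally weighted
   regression (tricube weights, degree 1) of logit-weight on probit
   coefficient is fitted with span starting at 0.75, widening in 0.05
   steps whenever the smoother is ill-posed (singular or
   ill-conditioned local systems, non-positive residual degrees of
   freedom), and falling back to ordinary least squares past span 1.
   Each local neighbourhood uses at least four anchors because the
   farthest carries zero tricube weight. Predictions outside the anchor
   range extrapolate the boundary local line (logged). The prediction
   standard error is the equivalent-kernel norm times the smoother's
   residual scale (under the OLS fallback, the standard regression
   prediction SE). No off-the-shelf smoother exposes both span control
   and prediction SEs at new points, so the smoother is implemented
   here and verified in the tests against a brute-force
   tricube-weighted least-squares oracle.

4. **Uncertainty.** For every impediment, 100 000 draws
   `inverse-logit(Normal(logit mean, prediction SE))` give the weight's
   mean and 95% UI. Each impediment uses an RNG stream keyed by its
   name and the run seed, so results are independent of processing
   order and bit-reproducible. For extremely skewed cases (very large
   SE near a boundary) the mean can mathematically fall outside the
   central 95% interval; this is logged rather than masked.

5. **Variants and diagnostics.** Six weight tables are produced:
   {VAS, TTO} × {all five anchors, without "respiratory distress",
   without "cancer: lung metastasis"}. The exclusion variants exist
   because the paired-comparison ranking of those two anchors can
   contradict their direct valuations; `check_rank_consistency` reports
   all such discordant anchor pairs. Subgroup comparisons use Welch
   two-sample t-tests per (method, impediment) across binary
   demographics (gender, age < 36, graduation < 2005, small-animal
   interest, livestock work) at α = 0.05, with degenerate zero-variance
   cells handled explicitly and undersized groups skipped with a
   reason.

## Synthetic surveys

The generator inverts the elicitation model so every stage can be tested
against known truth:

- True weights: uniform draws over (0.117, 0.857) — the span of the
  elicited tables — with death pinned at 0.56. The five anchor
  impediments get fixed truths 0.20 / 0.39 / 0.48 / 0.86 / 0.92,
  mirroring their designed role of covering the severity range; leaving
  them random lets them cluster, which no sensible study design would
  permit and which destabilises the anchoring step.
- Choices follow the Thurstonian model: P(first judged better) =
  Φ((s₂ − s₁)/scale) with s = logit(true weight) and unit scale (an
  optional cubic bend on the logit scale stresses the smoother against
  non-linear maps). A no-answer rate of 0.0036 reproduces roughly three
  unanswered items per 831 planned.
- The default respondent plan is 16/16/29 across versions A/B/C (61
  respondents, 828 answered comparisons). Each respondent's questions
  are drawn from a 300-pair random bank, the random-selection design
  recommended for paired-comparison valuation; narrow fixed banks leave
  impediments quasi-separated.
- Anchor noise: Gaussian with SD 15 VAS points and 2.5 TTO years
  (consistent with the dispersion of direct valuations at this scale),
  clipped to the instrument range; 2% of respondents are flagged
  infeasible to exercise filtering.
- Life tables derive from a Gompertz survival curve (newborn expectancy
  13.7 y, senescence rate 0.35/y) with residual expectancies obtained
  by numerical integration, so tables are internally coherent; the
  packaged `lifetable_synthetic.csv` is this construction frozen to
  CSV. It is a synthetic stand-in calibrated to a realistic canine
  lifespan, not a published actuarial table.

What passing the synthetic tests does **not** show: real respondents are
not exchangeable probit machines — they cluster, learn across the
questionnaire, and differ systematically by demographics; real
epidemiological inputs carry source heterogeneity that the fixtures'
placeholder `P_i`/`D_i` (curated, clinically plausible values — the
underlying case series are not public) do not capture. Recovery results
on simulated surveys therefore validate the pipeline's statistics, not
any particular published weight value.

## Problem sizes and reproducibility

The test suite runs the replicate-recovery experiment at 50 surveys of
61 respondents with 1 000 uncertainty draws per weight (ranking is
insensitive to the draw count); full runs default to 100 000 draws.
All randomness flows from explicit seeds through named RNG streams;
every output file records seed, draw count, variant and schema version
in a header comment, and identical configurations reproduce identical
bytes.

## Known limitations

- Pooled probit ignores respondent-level correlation; SEs are somewhat
  optimistic.
- With only 4–5 anchors the anchoring map is fragile by construction;
  the span-adaptation/OLS fallback makes it robust, not powerful.
- No comorbidity adjustment, age-weighting or time-discounting; no
  euthanasia mortality for the non-fatal disease models.
- The published weight tables and per-disease burden components shipped
  as fixtures are rounded to their printed precision.
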