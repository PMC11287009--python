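# Methods

## Disease-progression model

Progression is a time-homogeneous continuous-time Markov chain on a small
state space: the non-high 10-year ASCVD risk categories, the high-risk
category, and two absorbing states (ASCVD event, non-ASCVD death).
Transitions are bidirectional among non-high categories and between the
top non-high category and high; every transient state can reach both
absorbing states.  Time is measured in years since study entry, and rates
are per-year; homogeneity in time-since-entry is assumed throughout (no
age- or period-dependence of the intensities — sex-specific questions are
handled by fitting separate models on sex-filtered panels rather than by
covariates on rates).

The data are panel observations: risk categories are seen only at survey
visits, absorbing events carry exact dates.  The likelihood multiplies,
over consecutive record pairs, `P[a,b](dt)` for screen→screen pairs,
`sum_j P[a,j](dt) q[j,d]` over transient `j` for a pair ending in an
exactly dated absorbing event `d` (movement is free until the final jump,
which happens exactly at the event date), and `sum_j P[a,j](dt)` for
censoring (alive, category unknown).  A pure-panel variant
(`exact_event_times=False`) instead treats the absorbing state as
observed at the next scheduled visit, for comparison with fitting
conventions that discard registry dates; the exact-date mode is the
default because absorbing events in the emulated design come from
registry linkage.

### Numerics

* Transition probabilities are `expm(Q t)` (scaling-and-squaring Padé via
  SciPy).  During fitting, thousands of distinct event lags are needed per
  likelihood evaluation, so `P(t)` is evaluated through one
  eigendecomposition of `Q` per candidate (`P(t) = V e^{Λt} V⁻¹`), falling
  back to per-lag `expm` when the eigenvector matrix is ill-conditioned
  (condition number above 1e8).  The spectral route is verified against
  `expm` and against an independent uniformization oracle in the tests
  (1e-10 elementwise).
* Optimisation is BFGS over the logs of the allowed off-diagonal rates,
  which enforces positivity without constraints.  Initial rates are crude
  counts of observed direct transitions divided by person-time observed in
  the origin state, floored at 1e-4/year.  Convergence is declared when a
  BFGS restart improves the log-likelihood by a relative amount ≤ 1e-16,
  with a small-gradient check (relative to the log-likelihood scale) as a
  secondary guard; non-convergence is reported in the result object and
  the run log, never silently accepted.
* The covariance of the log-rates is the inverse of a central-difference
  Hessian of the negative log-likelihood at the optimum (pseudo-inverse,
  symmetrised).  Uncertainty on downstream quantities is propagated by
  multivariate-normal draws of the log-rates pushed through the entire
  screening/economics chain, summarised as percentile intervals.  The
  delta method is deliberately not used downstream because the
  person-years functional is only piecewise smooth in `Q`.

## Screening evaluation

A protocol gives each non-high category a whole-year screening interval;
high-risk individuals leave screening for treatment when found.  The
evaluation generator is the fitted `Q` with high→non-high rates removed
(the high diagonal re-balanced), reflecting the assumption that treated
high-risk individuals are not re-classified downward.

Person-years unidentified in high risk are accumulated by an event-driven
recursion over strata `(time of last screen, category observed then)`.
Between screens, the occupancy integral
`∫₀^Δ [e^{Qu}]_{i,high} du` is computed exactly with the Van Loan
augmented block-matrix exponential (cross-checked against trapezoidal
quadrature at fine resolution, 1e-6).  At a screen, surviving mass is
re-categorised by its current state: high mass is identified and stops
accruing unidentified time and screening costs; non-high mass is
rescheduled with the *new* category's interval (the schedule resets on
re-categorisation — this is the natural reading of interval-per-category
and makes the uniform reference a special case).  Design choices that the
source description leaves open, exposed as flags rather than silently
fixed:

* **Continuous versus annual accounting** — the default integrates
  occupancy continuously; `mode="annual"` applies one-year transition
  steps and accrues high occupancy by the trapezoid rule.
* **Screen at exactly the horizon** — not performed (the default), since
  a screen at year 10 can identify no one within the horizon.
* **The baseline categorisation screen at t = 0** — common to all
  protocols, hence not counted in screening volume; subsequent screens are
  weighted by surviving, not-yet-identified, non-absorbed mass (someone
  found high at a screen attends that screen).

Mass is conserved at every screen to 1e-8 relative (identified +
in-program + absorbed equals the initial cohort), person-years are
monotone in every interval, and a four-category model that is lumpable
onto a three-category one reproduces its results to 1e-8; all three are
enforced by tests.

## Health economics

Benefits and harms are linear in the person-year difference versus the
uniform 3-yearly reference: per 100,000 statin-treated person-years,
251.86 ASCVD events prevented, 225.17 QALYs gained, 85.81 diabetes and
34.37 myopathy cases caused; incremental statin cost 212.34 CN¥ per
person-year (low-delivery variant 70.78), health check 30.00 CN¥ (all
2019 CN¥).  Sign conventions are explicit in the field names: earlier
identification (positive Δ person-years) *adds* statin cost; savings must
come from reduced screening volume.  No discounting is applied by default
(a discount-rate hook exists, set to 0, because the source analysis
states none).  The optimal protocol maximises events prevented among
those with non-positive total-cost delta (ties: larger saving, then fewer
screens); if none qualifies, the reference is returned flagged.

Whether screens for individuals after an ASCVD event or death should be
costed is not specified in the source description; here screens are
weighted by surviving unidentified mass, so the dead attend none.

## Risk equation

The 10-year risk is the usual survival-equation form
`1 − S0^exp(lp − lp̄)` with sex-specific coefficients, reference means and
baseline survival `S0`, all treated as configuration: published
coefficient sets can be supplied, and the shipped set
(`fixtures.example_risk_equation`) is synthetic and documented as such.
Recalibration to a target population replaces `S0` with the unique value
matching the cohort's mean predicted risk to an observed 10-year risk
(Brent root-find, tolerance 1e-10), per sex stratum; slopes are left
untouched.  Mean-risk matching was chosen over decile-wise matching
because a single scalar target identifies a single scalar parameter;
finer calibration targets can be expressed by recalibrating within
user-defined strata.  Category cut-offs are closed on the left: a risk
exactly at a threshold belongs to the higher category.

## Synthetic cohort generator

The generator emulates a biobank panel design: a baseline survey everyone
attends, resurveys at years 4 and 9 attended with probabilities 0.66 and
0.84 (matching the attendance pattern of the emulated design), exactly
dated absorbing events, and administrative censoring at 12.8 years.  An
exclusion option (`per_subject`) drops subjects who attended no resurvey,
since a cohort defined by resurvey participation could have been formed
either way; the default keeps everyone because the acceptance experiments
condition only on the observation schedule.

The calibrated fixture (`fixtures.ckb_like_generator`) sets, for the
three-category scheme: total exit rates 1/10.5 per year from low and
1/5.3 from intermediate; jump shares into ASCVD of 2.2% (low), 4.1%
(intermediate) and 10.4% (high); reversal shares 7.4%
(intermediate→low) and 8.8% (high→intermediate); and a baseline category
mix of 49.8/20.5/29.7% low/intermediate/high.  Values with no published
anchor are fixed once at documented levels: small non-ASCVD-death shares
from low (3.8%) and intermediate (4.5%), the remaining low-state shares
split 90%/4% between intermediate and high, and a high-state mean sojourn
of 6 years.  With only three exits from high, its jump shares must sum to
one, so the residual 80.8% goes to non-ASCVD death — a consequence of the
high-risk category being dominated by older individuals.  The
four-category fixture splits the intermediate band in two with a faster
upper band (mean sojourn 3.5 years); only the three-category rates carry
published anchors.

What the generator does **not** emulate: age structure and cohort ageing
(rates are homogeneous in time-since-entry), regional or cluster
sampling, loss to follow-up, misclassification of the observed category,
and any dependence of attendance on health status.  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the stated model, not robustness of the model
to real-data violations of it.

## Problem sizes

Parameter-recovery experiments (and `scripts/acceptance.py`) use 30,000
subjects per scheme, the cohort size at which recovered sojourn times sit
within ~1–2% of truth.  The confidence-interval coverage experiment uses
20 replicates of 4,000 subjects, a size at which the asymptotic normal
intervals are already well calibrated, keeping the whole suite fast.  The
full default pipeline — both schemes, 27 protocols, 500 uncertainty draws
— completes in roughly a minute on one CPU.

## Known limitations

* The printed jump shares are interpreted as embedded next-jump
  probabilities; if they were instead fixed-horizon transition
  probabilities, the calibration targets would differ.  The package
  computes and labels both (`jump_probabilities` versus
  `transition_matrix`), and uses the jump interpretation only for its own
  fixtures.
* The four-category fitting structure allows a lower-intermediate
  reversal from the upper intermediate band that the fixture sets to
  zero; its estimate is then weakly identified, which widens (honestly)
  the propagated percentile intervals for four-category protocols.
* Covariates on intensities, hidden-Markov misclassification layers and
  time-inhomogeneous rates are out of scope.
* Initial cohorts are closed: no entries, ageing-in, or competing
  screening programmes over the 10-year horizon.
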