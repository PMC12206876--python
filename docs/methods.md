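# Methods

## Data model and counting unit

A deduplicated case is one `SafetyReport`: demographics, a list of drug
entries with role codes (PS primary suspect, SS secondary suspect, C
concomitant, I interacting) and therapy-start dates, and a *set* of MedDRA
preferred terms (PT). Duplicate PTs within a report are collapsed; the
counting unit for every 2×2 table is the (report, PT) pair, so a report
with k distinct PTs contributes k pairs. At SOC level a report contributes
at most one pair per distinct system organ class its PTs map to. This pair
convention is what makes an "event total" larger than the report total and
is assumed by all conservation invariants (Σa over terms = index pair
total).

Deduplication keeps, within each `caseid` cluster, the row maximizing
(`fda_dt`, `primaryid`) lexicographically — most recent FDA receive date,
ties broken by highest primaryid; clusters with missing receive dates fall
back to primaryid order with a warning. The operation is idempotent and
child tables (DRUG/REAC/THER/INDI) are restricted to surviving primaryids.

Field conventions: age unit codes YR/MON/WK/DY/DEC/HR convert to years by
×1, ÷12, ÷52.143, ÷365.25, ×10, ÷8766; a present age without a recognized
unit is treated as years and flagged. Age bins are half-open [0,18),
[18,65), [65,85), [85,∞). Occupation codes MD/PH/HP/RN/OT map to
healthcare-professional, CN/LW to non-healthcare-professional, anything
else to missing. Dates are carried as digit strings; calendar arithmetic
only ever uses full 8-digit dates, and `report_year` needs at least a
4-digit year. Drug names are uppercased, punctuation-stripped and resolved
through an exact-match synonym table — no fuzzy matching, so normalization
is deterministic and auditable.

## Disproportionality statistics

Given cells (a, b, c, d), N = a+b+c+d, E = (a+b)(a+c)/N:

- ROR = ad/bc with the Wald interval on the log scale. Any zero cell
  triggers a 0.5 continuity add to all four cells and a `corrected` flag on
  the row, keeping every term reportable while marking the correction.
- PRR = [a/(a+b)]/[c/(c+d)]; Pearson χ² without Yates correction by
  default (a config flag enables it). c = 0 yields a flagged infinite PRR
  with χ² computed on the continuity-added table.
- IC = log₂[(a+½)/(E+½)] — the shrunk observed/expected ratio in bits —
  with the Norén closed-form lower bound
  IC025 = IC − 3.3(a+½)^(−1/2) − 2.0(a+½)^(−3/2). This closed-form BCPNN
  is used rather than the full prior-propagation network; the exact
  posterior-quantile IC is a documented extension point.
- Gating: per-method flags (ROR lower > 1; PRR ≥ 2 ∧ χ² ≥ 4; IC025 > 0;
  EBGM05 > 2), support floor a ≥ 3, combined with OR by default (AND
  available). No multiple-testing adjustment — gating is threshold-based by
  design, and the null false-positive rate of the combined gate is itself a
  tested quantity (a few percent on a null synthetic corpus).

An exact algebraic identity links the two ratio statistics:
ROR ⋛ PRR ⇔ ROR ⋛ 1 ⇔ ad ⋛ bc. The test suite asserts it both on random
tables and on every table the pipeline computes; it also holds in the
reference tables this package was validated against (the
PRR-inversion consistency checks in `scripts/acceptance.py`).

## Gamma-Poisson shrinker

Counts follow a ~ Poisson(λE) with a two-component gamma mixture prior on
the relative reporting rate λ. Hyperparameters (α₁, β₁, α₂, β₂, w) are
fitted by maximizing the resulting negative-binomial mixture marginal over
all tables of a level, starting from the canonical (0.2, 0.1, 2.0, 4.0,
1/3). The search runs in log/logit space with Nelder–Mead: the marginal
surface has a degenerate ridge (label switching, point-mass limits) where
finite-difference gradients misbehave, and the simplex search converges
robustly on simulation checks (single-component recovery within 10% on
5,000 null pairs). `maxiter=0` returns the initial prior unchanged;
non-convergence returns the best iterate with `converged=False`.

Conjugacy gives the posterior mixture q·Gamma(α₁+a, β₁+E) +
(1−q)·Gamma(α₂+a, β₂+E) with q from the marginal likelihood ratio.
EBGM = exp E[ln λ|a] (geometric mean, via digamma), EBGM05 solves the
mixture CDF = 0.05 by Brent root finding bracketed between the component
quantiles (CDF at EBGM05 accurate to 1e−8). A brute-force oracle
(`mgps.ebgm_oracle`) integrates the unnormalized posterior on a 200k-point
log grid; closed form and oracle agree to < 1e−6 relative on random draws
— the oracle exists only for verification and never feeds the pipeline.

Because the printed EBGM column of the reference analysis coincides with
2^IC in every checked row, a simplified mode (`ebgm_mode="ic"`) reporting
EBGM = 2^IC and EBGM05 = 2^IC025 is provided to reproduce that convention;
the default remains the full shrinker.

On synthetic corpora whose non-planted terms all have true λ = 1, the
fitted prior legitimately collapses toward point masses (a spike near 1
plus a component at the planted ratio); posteriors then have almost no
spread and EBGM05 ≈ EBGM. This is faithful empirical Bayes on data that
truly has a two-point rate structure, not a numerical defect; real
databases, with a continuum of rates, yield diffuse priors.

Note also that with a small vocabulary and a large index share of the
corpus, E absorbs part of a planted excess through the margins, so
EBGM and IC sit systematically below the ROR/PRR for the same planted
relative risk; the detection tests therefore score the gate, and the
RR-consistency test scores the ROR.

## Time-to-onset

TTO = event onset date − earliest full-date primary-suspect therapy start,
in days. Exclusions (missing/partial dates, tto ≤ 0 including same-day
onsets — Weibull support is strictly positive) are tallied per reason. The
Weibull fit is uncensored maximum likelihood (delegated to
`lifelines.WeibullFitter`), with 95% CIs computed by the delta method on
log(scale) and log(shape) so bounds stay positive. Hazard classification:
shape CI above/below 1 → wear-out/early-failure, straddling → random.
Cross-checks: scipy's `weibull_min.fit(floc=0)`, a brute-force likelihood
grid at n = 50, scale equivariance, and a 200-replicate bias bound
(|bias| < 0.02 at n = 1848).

## Subgroups and sensitivity

Subgroup analyses re-partition the corpus by sex or age bin and run the
identical pipeline per level against a *within-stratum* background — the
comparator is restricted to the same level, which avoids confounding a
stratum-specific signal with the stratum's overall reporting profile (a
global-background variant would be a one-line change; within-stratum is
the default and the tested behaviour). Reports missing the stratifying
variable are excluded from every level and counted. An `age_spec`
preset optionally merges the two oldest bins into a single ≥65 level.

The sensitivity analysis retains index reports whose co-medications all
belong to a partner-drug allowlist (default: the eight platinum-partner
agents commonly co-prescribed — gemcitabine, pemetrexed, docetaxel,
paclitaxel, vinorelbine, pembrolizumab, atezolizumab, amivantamab);
reports with any other concomitant drug are excluded and counted. The
filter is monotone in the allowlist.

## Synthetic corpus generator

`synth.generate` emits DEMO/DRUG/REAC/THER files in the ingest dialect, a
PT→SOC table, and a JSON truth sidecar (planted effects, duplicate
clusters, index membership, onset law). Defaults describe one standard
study condition: 20,000 reports; 200 PTs across 20 SOCs with Zipf-like
background frequencies; index-drug share 0.24 (a cohort of ~4,800, the
scale of the reference analysis); ~3.1 events per report (truncated
geometric, matching the reference events-per-report ratio); sex
M/F/missing = 0.466/0.306/0.228, age ~ N(66, 13²) with 29.7% missing,
reporter and country margins near the reference table; duplicate rate
0.05; onset lag Weibull(scale 51.72 d, shape 0.78) with 45% missing and
10% partial onset dates (reproducing a realistic ~40% TTO yield). Events
are drawn per report by a truncated-geometric count and weighted sampling
without replacement; index reports scale each planted PT's weight by its
relative risk (optionally only within a sex/age carrier subgroup) and
renormalize.

Two generator simplifications matter for interpretation: PTs are sampled
independently given the drug (no within-report event correlation, unlike
real syndromic reporting), and onset lags are rounded to whole days and
truncated at 365 d (~1% of the reference law's mass), which biases a
refitted shape up by ~0.02 at n ≈ 2,000 — inside every tolerance used.
Passing tests therefore demonstrate estimator and pipeline correctness
under a clean reporting model, not robustness to real-world reporting
artifacts (term miscoding, drug-name noise, correlated events,
indication-channelled backgrounds).

All randomness flows from one integer seed; identical configs produce
byte-identical files. Truth is always read from the sidecar, never
re-derived from the generated tables.

## Problem sizes in the test suite

The standard fixtures use one 20,000-report corpus (with a planted
RR = 10 term) and one null corpus of the same size; replicated checks use
smaller corpora (100 × 1,500 reports for ROR consistency, 10 × 6,000 for
the sex-restricted carrier-stratum property) and 20–200 replicates of
n = 1,848 Weibull samples. These sizes give the detection and recovery
properties comfortable margins while the full suite runs in a few minutes
on one CPU.

## Known limitations

- The BCPNN is the closed-form shrinkage IC, not the full propagation
  network; MGPS expected counts are unstratified (subgroup effects are
  handled by corpus subsetting, not by stratified E).
- No interval censoring or censoring model in the TTO fit — spontaneous
  reports are events by construction.
- Indication-based cohort restriction is available as an optional filter
  but off by default; how such restrictions are best operationalized on
  spontaneous reports is analysis-specific.
- The printed-precision EBGM05 conventions of published tables vary;
  both the full-posterior percentile and the 2^IC025 convention are
  provided explicitly rather than guessing a single one.
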