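# pvsignal

Signal detection for spontaneous adverse-event reporting data in the style
of the FDA Adverse Event Reporting System (FAERS).

Pharmacovigilance teams mine spontaneous-report databases for drug–event
combinations that are reported *disproportionately* often: the database has
no denominator of exposed patients, so the only available comparison is how
often an event is reported with the drug of interest versus with every other
drug. `pvsignal` packages that workflow end to end for an index drug
(e.g. carboplatin in lung-cancer pharmacovigilance): quarterly-file
ingestion and case deduplication, four disproportionality statistics with
signal gating at MedDRA preferred-term (PT) and system-organ-class (SOC)
level, demographic subgroup and co-medication sensitivity re-analysis,
Weibull time-to-onset modelling, and a synthetic-corpus generator with a
ground-truth sidecar so the whole pipeline is testable without access to a
real extract.

## The statistics

For a drug–event pair, with the (report, term) pair as counting unit,

|            | event of interest | other events |
|------------|-------------------|--------------|
| index drug | a                 | b            |
| other drugs| c                 | d            |

and N = a+b+c+d, the engine computes

- **ROR** = (a·d)/(b·c), with the 95% Wald interval
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); zero cells get the
  Haldane–Anscombe 0.5 add (flagged).
- **PRR** = [a/(a+b)] / [c/(c+d)] with the Pearson χ² statistic
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)].
- **IC** (BCPNN information component) = log₂[(a+½)/(E+½)] with
  E = (a+b)(a+c)/N, and the Norén lower bound
  IC025 = IC − 3.3(a+½)^(−1/2) − 2.0(a+½)^(−3/2).
- **EBGM** (gamma-Poisson shrinker): a ~ Poisson(λE) with a two-component
  gamma mixture prior on λ fitted by maximizing the negative-binomial
  marginal over all tables; EBGM = exp E[ln λ | a] and EBGM05 is the
  posterior 5th percentile.

A term is gated **positive** when at least one method exceeds its threshold
(defaults: ROR lower bound > 1; PRR ≥ 2 with χ² ≥ 4; IC025 > 0;
EBGM05 > 2; all require a ≥ 3).

Time-to-onset (days from primary-suspect therapy start to event onset) is
fitted with a two-parameter Weibull law by maximum likelihood; a shape CI
entirely below 1 indicates an early-failure hazard (risk concentrated soon
after initiation).

## Worked example

```python
from pvsignal import synth, ingest, signal_engine as se, tto_weibull as tw

cfg = synth.SynthConfig(n_reports=5000, seed=11,
                        planted_signals=(synth.PlantedSignal("PT150", 8.0),))
paths = synth.generate(cfg, "demo")

raw = ingest.read_quarter({k: paths[k] for k in ("demo", "drug", "reac", "ther")})
reports, _ = ingest.assemble_reports(ingest.deduplicate(raw),
                                     hierarchy=ingest.load_hierarchy(paths["hierarchy"]))
index, background = ingest.select_index_cohort(reports, "CARBOPLATIN")
rows = se.compute_signals(se.build_tables(index, background))
top = next(r for r in rows if r.term == "PT150")
print(f"PT150: a={top.a}  ROR={top.ror:.2f} ({top.ror_low:.2f}-{top.ror_high:.2f})  "
      f"PRR={top.prr:.2f} (chi2={top.chi2:.1f})  IC={top.ic:.2f} ({top.ic025:.2f})  "
      f"EBGM={top.ebgm:.2f} ({top.ebgm05:.2f})  positive={top.positive}")

fit = tw.fit_weibull(tw.extract_tto(index, "CARBOPLATIN"))
print(f"TTO: n={fit.n}  scale={fit.scale_alpha:.1f} d ({fit.scale_ci[0]:.1f}-{fit.scale_ci[1]:.1f})  "
      f"shape={fit.shape_beta:.2f} ({fit.shape_ci[0]:.2f}-{fit.shape_ci[1]:.2f})  {fit.hazard_type}")
```

prints

```
PT150: a=62  ROR=8.23 (5.13-13.20)  PRR=8.11 (chi2=108.4)  IC=1.55 (1.13)  EBGM=2.98 (2.98)  positive=True
TTO: n=540  scale=50.5 d (45.1-56.5)  shape=0.79 (0.74-0.84)  early-failure
```

The planted term (relative risk 8 on `PT150`) is recovered: 62 index
reports carry it, the ROR/PRR sit near 8, and all four methods flag it.
EBGM is smaller because it is shrunk toward the database-wide expectation —
the deliberate behaviour of the empirical-Bayes estimator. The onset
intervals were generated from a Weibull law with scale 51.72 d and shape
0.78; the refit recovers both and classifies the hazard as early failure
(shape CI below 1: risk is highest right after therapy initiation).

The same pipeline runs from the shell:

```
pvsignal all -c config.yaml          # simulate -> ingest -> signals -> tto -> subgroup -> sensitivity
pvsignal signals -c config.yaml      # just the disproportionality tables
```

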