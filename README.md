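# pvsignal

Disproportionality signal mining for spontaneous adverse-event report
extracts — the standard pharmacovigilance workflow applied, for example, to
FAERS exports produced by OpenVigil-style front ends.

Spontaneous-reporting databases have no denominator: you cannot estimate
incidence, only asymmetry of reporting. For a drug–event pair the
deduplicated reports are laid out in a 2×2 table

|              | target AE | other AEs |
|--------------|-----------|-----------|
| target drug (PS) | a     | b         |
| other drugs  | c         | d         |

and two disproportionality measures are computed with lognormal 95%
confidence intervals:

- **ROR** (reporting odds ratio) = `ad / bc`,
  CI `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`
- **PRR** (proportional reporting ratio) = `[a/(a+b)] / [c/(c+d)]`,
  CI `exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))`)

A pair is flagged as a **signal** when jointly `a ≥ 3`, the ROR CI lower
bound `> 1`, and `PRR > 2`. Signals are ranked by report count, aggregated
into MedDRA System Organ Classes (each PT counted under its primary SOC),
and SOC-level RORs are computed by treating "any member PT present" as the
event. χ² (Pearson, optionally Yates-corrected) is reported alongside.

The package is aimed at pharmacovigilance analysts and methodologists who
want this pipeline reproducible end to end **offline**: it therefore also
ships

- a **synthetic extract generator** that emulates FAERS structure (one PS
  drug per case, Zipf-tailed event frequencies, missing demographics, case
  versioning) with associations *planted* on the odds scale so the expected
  table has an exactly known ROR — every pipeline stage can be validated
  against closed-form ground truth; and
- a **summary inversion** tool: given a published row `(a, PRR, ROR, 95% CI)`
  the remaining cells `b, c, d` are identified in closed form
  (`b = a(PRR−1)/(ROR−PRR)`, then c and d from the CI width), with
  internal-consistency checks that detect transcription errors in printed
  tables (e.g. a row with PRR > ROR > 1 is impossible for any positive
  table).

## Worked example

```python
from pvsignal import DisproportionalityModel, simulate

scenario = simulate.default_scenario(seed=7)      # 20,000 cases; one planted pair
reports = simulate.generate_reports(scenario)     # canonical report frame
model = DisproportionalityModel(
    reports,
    drugs=["voriconazole", "posaconazole", "isavuconazole"],
    soc_map=simulate.scenario_soc_map(scenario),
)
res = model.fit()
print(res.summary(top_n=5))
```

```
Disproportionality analysis
===========================
reports: 20000 cases in, 20000 after dedup; 352 (drug, PT) pairs; 5 signals
criteria: a >= 3, ROR CI low > 1.0, PRR > 2.0

voriconazole: 1 signal(s)
  PT                                       a       PRR       ROR              95% CI
  ----------------------------------------------------------------------------------
  event_030                              280     4.494     4.761       (4.001-5.664)

posaconazole: 0 signal(s)

isavuconazole: 4 signal(s)
  PT                                       a       PRR       ROR              95% CI
  ----------------------------------------------------------------------------------
  event_093                                6     2.658     2.681       (1.171-6.143)
  ...
```

The scenario planted `(voriconazole, event_030)` at ROR = 5 and the fitted
model recovers it: a = 280 reports, ROR 4.761 (95% CI 4.001–5.664), the only
voriconazole signal. The analytic expectation for that pair,
`simulate.expected_table(scenario, "voriconazole", "event_030")`, is
(a, b, c, d) ≈ (291.3, 3708.7, 247.4, 15752.6) — ROR exactly 5. The four
isavuconazole "signals" are the kind of weak false positives a joint
a ≥ 3 / CI / PRR rule admits at this scale; the null false-signal rate is
itself one of the quantities the validation studies measure.

Inverting a published row (the strongest printed voriconazole signal,
actinic keratosis: a = 78, PRR 105.868, ROR 106.965, CI 84.915–134.740):

```python
from pvsignal import invert_summary
inv = invert_summary(78, 105.868, 106.965, 84.915, 134.740)
inv.rounded.cells()          # (78, 7456, 1090, 11146837)
max(inv.residuals.values())  # 0.00017 -> recomputed stats match to 0.017%
```

i.e. the printed row implies a background of ≈ 11.1 M comparator reports —
the size of the cleaned FAERS snapshot such studies query.

The same pipeline is scriptable from the shell
(`pvsignal signals|demographics|soc|soc-ror|simulate|invert`, YAML config,
deterministic outputs; see `pvsignal --help`).

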