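# nhrs-barometer

A scoring engine for the **African National Health Research System (NHRS)
barometer** — the composite indicator used to track how well a country's
health research system performs, built for health-policy analysts who run
or re-analyse NHRS surveys.

A national health research system is scored on four functions —
leadership & governance, developing & sustaining resources, producing &
utilizing research for health (R4H), and financing — through 17
sub-functions. Thirteen are binary existence indicators (a national R4H
policy, a research ethics committee, a knowledge translation platform, …)
scored 1 if the structure exists and 0 otherwise. Four are continuous:
research staff per 100,000 population, universities conducting R4H per
million population, peer-reviewed publications per 100,000 population,
and the share of the health ministry budget allocated to R4H.

Each sub-function's actual score *x* is normalised against goalposts
(min, max), Human-Development-Index style:

```
SFI = (x − min) / (max − min)          clamped to [0, 1]
```

Binary goalposts are (0, 1); the university and publication goalposts are
the cohort maxima of the 2018 African Region survey (5.39, Cabo Verde;
12.514, South Africa); the budget-share goalpost is the regional policy
target of 2%. The overall barometer score is the unweighted mean of all
17 indices times 100:

```
NHRS_BSCORE = ( Σᵢ SFIᵢ / n_SF ) × 100%
```

and is banded: 0% nonexistent, (0, 50)% below average, 50% average,
(50, 100)% above average, 100% optimal. Function scores are the means of
their own sub-function indices; performance gaps are `100 − score`.

The package also compares assessment rounds (absolute percentage-point
and relative percent-of-baseline change), derives cohort goalposts (the
benchmark-country rule), and simulates synthetic country cohorts with
known generating parameters for end-to-end testing.

## Worked example

```python
from nhrs_barometer import build_default_schema, mauritius_2020, score_country

schema = build_default_schema()          # the canonical 17-indicator schema
card = score_country(schema, mauritius_2020())
print(f"overall {card.overall_score:.2f}%  band {card.band.value}")
for fid, s in card.function_scores.items():
    print(f"  {fid:<24} {s:6.2f}%  gap {card.gaps[fid]:.2f}%")
```

prints

```
overall 60.84%  band above_average
  leadership_governance     50.00%  gap 50.00%
  developing_resources      76.95%  gap 23.05%
  producing_utilizing       52.04%  gap 47.96%
  financing                 58.20%  gap 41.80%
```

Mauritius 2020: an above-average system overall (60.84%, 39.16% short of
optimal), dragged down by four absent governance structures (policy,
strategic plan, prioritized agenda, research management forum), a thin
research workforce (index 0.0316) and under-target research financing
(0.328% of the health budget against the 2% goalpost, index 0.164).

The same run is available from the shell:

```sh
nhrs-barometer score --obs src/nhrs_barometer/data/mauritius_2020.csv --out out/
nhrs-barometer compare --baseline src/nhrs_barometer/data/mauritius_2018_scores.csv \
                       --current out/Mauritius_2020_scorecard.json --out out/
nhrs-barometer simulate --seed 7 --n-countries 20 --out out/
nhrs-barometer validate
```

## Layout

| module | contents |
|---|---|
| `nhrs_barometer.schema` | schema types, the default 17-indicator schema, JSON/YAML IO, validation |
| `nhrs_barometer.scoring` | actual scores: binary rule, per-capita rates, budget share; observation CSV IO |
| `nhrs_barometer.barometer` | min–max indices, function/overall scores, bands, gaps, `score_country` |
| `nhrs_barometer.comparison` | temporal change analysis, cohort goalpost derivation |
| `nhrs_barometer.simulate` | synthetic cohort generator and closed-form expected scores |
| `nhrs_barometer.cli` | `nhrs-barometer` console script (score / compare / simulate / validate) |
| `nhrs_barometer.data` | default schema, Mauritius fixtures, column dictionary, JSON Schema |

See `docs/methods.md` for the model, numerical conventions, and the
simulator's design.
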