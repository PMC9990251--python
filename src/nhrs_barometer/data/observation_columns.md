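# Observation table column dictionary

One row per country-year, CSV, UTF-8, comma-separated, header row.

## Base columns (always required)

| column | type | meaning |
|---|---|---|
| `country` | text | country name (used in outputs and diagnostics) |
| `year` | integer | assessment year |
| `population` | positive integer | total population (persons) |
| `r4h_budget` | non-negative real | government allocation to research for health, national currency units |
| `total_health_budget` | positive real | total health ministry budget, same currency |

## Indicator columns

One column per indicator, named by indicator id. Binary indicators hold a
0/1 flag (blank = missing; strict mode rejects, permissive mode scores 0).
Count-based continuous indicators hold the **raw head count** — the
per-capita rate is computed at scoring time from `population`:

| column | holds | scaling applied at scoring |
|---|---|---|
| `r4h_policy` … `budget_line` (13 binary ids) | 0/1 flag | none |
| `staff_per_100k` | staff head count (full- and part-time at parity) | × 100,000 / population |
| `universities_per_million` | universities/colleges conducting R4H | × 1,000,000 / population |
| `pubs_per_100k` | peer-reviewed publications in the 12-month window | × 100,000 / population |

The budget-share indicator (`budget_share_pct`) has **no column of its
own**: it is computed as `r4h_budget / total_health_budget × 100`.

Columns not matching any schema indicator are rejected in strict mode and
ignored with a warning in permissive mode.
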