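"""Scorecard and comparison exports: JSON, CSV, and a fixed-width text table.

Reports print scores at 2 decimals and indices at 3–4 decimals, the
granularity at which published scorecards present them; function scores
are shown both as a fraction and a percent ("0.50 (50%)" style).
"""

from __future__ import annotations

import json
from io import StringIO
from typing import Iterable

import pandas as pd

from .barometer import ScoreCard
from .comparison import ComparisonResult, TemporalComparison
from .schema import BarometerSchema


def _fmt(value: float, nd: int) -> str:
    s = f"{value:.{nd}f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def scorecard_to_dict(card: ScoreCard) -> dict:
    return {
        "country": card.country,
        "year": card.year,
        "precision_mode": card.precision_mode,
        "sub_indices": [
            {
                "indicator_id": s.indicator_id,
                "actual": s.actual,
                "index": s.index,
                "clamped": s.clamped,
            }
            for s in card.sub_indices
        ],
        "index_sum": card.index_sum,
        "function_scores": dict(card.function_scores),
        "overall_score": card.overall_score,
        "band": card.band.value,
        "gaps": dict(card.gaps),
    }


def scorecard_to_json(card: ScoreCard) -> str:
    return json.dumps(scorecard_to_dict(card), indent=2, sort_keys=True) + "\n"


def scorecard_from_json(text: str) -> dict:
    """Parse a scorecard JSON export back into a plain dict."""
    return json.loads(text)


def scorecard_to_csv(card: ScoreCard, schema: BarometerSchema) -> str:
    """Flat CSV: one row per sub-function, then summary rows."""
    imap = schema.indicator_map
    rows = []
    for s in card.sub_indices:
        ind = imap[s.indicator_id]
        rows.append(
            {
                "row_type": "sub_function",
                "id": s.indicator_id,
                "label": ind.label,
                "function_id": ind.function_id,
                "actual_score": round(s.actual, 3),
                "goalpost_min": ind.goalpost_min,
                "goalpost_max": ind.goalpost_max,
                "index": round(s.index, 4),
                "clamped": s.clamped,
                "score_pct": "",
            }
        )
    for fn in schema.functions:
        rows.append(
            {
                "row_type": "function_score",
                "id": fn.id,
                "label": fn.name,
                "function_id": fn.id,
                "actual_score": "",
                "goalpost_min": "",
                "goalpost_max": "",
                "index": round(card.function_scores[fn.id] / 100.0, 4),
                "clamped": "",
                "score_pct": round(card.function_scores[fn.id], 2),
            }
        )
    rows.append(
        {
            "row_type": "overall_score",
            "id": "overall",
            "label": f"Overall NHRS barometer score ({card.band.value})",
            "function_id": "",
            "actual_score": "",
            "goalpost_min": "",
            "goalpost_max": "",
            "index": round(card.overall_score / 100.0, 4),
            "clamped": "",
            "score_pct": round(card.overall_score, 2),
        }
    )
    return pd.DataFrame(rows).to_csv(index=False)


def render_scorecard(card: ScoreCard, schema: BarometerSchema) -> str:
    """Fixed-width text scorecard in the conventional published layout:
    sections per function with actual/max/min/index columns, a function
    average line per section, and the overall score line."""
    imap = schema.indicator_map
    by_id = {s.indicator_id: s for s in card.sub_indices}
    width = 78
    out = StringIO()
    title = f"NHRS barometer scorecard — {card.country} {card.year}"
    out.write(title + "\n")
    out.write("=" * width + "\n")
    header = f"{'Sub-function':<44}{'Actual':>8}{'Max':>8}{'Min':>6}{'Index':>10}"
    out.write(header + "\n")
    out.write("-" * width + "\n")
    for section, fn in zip("ABCD", schema.functions):
        out.write(f"{section}. {fn.name}\n")
        for iid in fn.indicator_ids:
            ind, s = imap[iid], by_id[iid]
            label = ind.label if len(ind.label) <= 39 else ind.label[:36] + "..."
            flag = "*" if s.clamped else ""
            out.write(
                f"  {ind.order:>2}. {label:<39}{_fmt(s.actual, 3):>7}"
                f"{_fmt(ind.goalpost_max, 3):>8}{_fmt(ind.goalpost_min, 0):>6}"
                f"{s.index:>9.4f}{flag}\n"
            )
        score = card.function_scores[fn.id]
        out.write(
            f"  Average '{fn.name}' score: "
            f"{score / 100:.4f} ({_fmt(round(score, 2), 2)}%)\n"
        )
        out.write("-" * width + "\n")
    out.write(
        f"Overall NHRS barometer score "
        f"(({_fmt(round(card.index_sum, 4), 4)} / {len(card.sub_indices)}) x 100%): "
        f"{card.overall_score:.2f}%\n"
    )
    out.write(f"Performance band: {card.band.value}   ")
    out.write(f"Gap to optimal: {card.gaps['overall']:.2f}%\n")
    if any(s.clamped for s in card.sub_indices):
        out.write("* index clamped to [0, 1]\n")
    return out.getvalue()


def comparisons_to_csv(result: ComparisonResult | Iterable[TemporalComparison]) -> str:
    comps = result.comparisons if isinstance(result, ComparisonResult) else tuple(result)
    rows = [
        {
            "label": c.label,
            "baseline_year": c.baseline_year,
            "baseline_score": c.baseline_score,
            "current_year": c.current_year,
            "current_score": c.current_score,
            "abs_change_pp": round(c.absolute_change, 4),
            "rel_change_pct": "" if c.relative_change is None else round(c.relative_change, 2),
        }
        for c in comps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "baseline_year", "baseline_score", "current_year",
            "current_score", "abs_change_pp", "rel_change_pct",
        ],
    ).to_csv(index=False)


def render_comparisons(result: ComparisonResult) -> str:
    out = StringIO()
    out.write(f"{'Label':<24}{'Baseline':>12}{'Current':>12}{'Δ pp':>10}{'Δ %':>12}\n")
    out.write("-" * 70 + "\n")
    for c in result.comparisons:
        rel = "n/a" if c.relative_change is None else f"{c.relative_change:+.2f}"
        out.write(
            f"{c.label:<24}{c.baseline_score:>12.2f}{c.current_score:>12.2f}"
            f"{c.absolute_change:>+10.2f}{rel:>12}\n"
        )
    for label in result.only_baseline:
        out.write(f"{label:<24}  (baseline only — incomparable)\n")
    for label in result.only_current:
        out.write(f"{label:<24}  (current only — incomparable)\n")
    return out.getvalue()
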