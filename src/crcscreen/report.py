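"""Publication-style validation report: characteristics, stratification,
performance, reclassification and resource-load tables, as plain text and
deterministic JSON (with a shipped structural schema)."""

from __future__ import annotations

import json
import math
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import stats
from .cohort import Cohort, CAN
from .scores import (
    APCS, HIGH, NON_HIGH, ScoreDefinition, apply_score, builtin_definitions,
    get_definition,
)

__all__ = [
    "REPORT_SCHEMA", "characteristics_table", "validate_cohort",
    "render_text", "bundle_to_json", "conforms_to_schema",
]

_AGE_BANDS = ((50, 54), (55, 59), (60, 64), (65, 69), (70, 74))
_BMI_CATS = (("<23", lambda b: b < 23), ("23-25", lambda b: 23 <= b < 25), (">=25", lambda b: b >= 25))


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def characteristics_table(cohort: Cohort) -> pd.DataFrame:
    """Cohort characteristics as category counts and percentages."""
    n = len(cohort)
    rows: list[dict] = []

    def add(characteristic: str, category: str, count: int) -> None:
        rows.append({
            "characteristic": characteristic, "category": category,
            "n": count, "pct": 100.0 * count / n if n else math.nan,
        })

    for lo, hi in _AGE_BANDS:
        add("age", f"{lo}-{hi}", sum(lo <= r.age <= hi for r in cohort))
    add("sex", "male", sum(r.sex == "male" for r in cohort))
    add("sex", "female", sum(r.sex == "female" for r in cohort))
    add("smoking", "current_or_past", sum(bool(r.smoker) for r in cohort))
    for label, pred in _BMI_CATS:
        add("bmi", label, sum(r.bmi is not None and pred(r.bmi) for r in cohort))
    add("diabetes", "yes", sum(bool(r.diabetes) for r in cohort))
    add("family_history_crc", "yes", sum(bool(r.family_history) for r in cohort))
    add("outcome", "CAN", sum(r.outcome == CAN for r in cohort))
    return pd.DataFrame(rows)


def _resolve(names: Optional[Sequence[str]]) -> list[ScoreDefinition]:
    if names is None or list(names) == ["all"]:
        return list(builtin_definitions())
    return [get_definition(n) for n in names]


def validate_cohort(
    cohort: Cohort,
    score_names: Optional[Sequence[str]] = None,
    comparator: str = APCS,
    level: float = 0.95,
    meta: Optional[Mapping] = None,
) -> dict:
    """Run the full validation pipeline on an eligible cohort.

    Returns a JSON-serialisable bundle with one section per published-table
    analogue.  The cohort must contain both outcome classes; the comparator
    must be among the requested scores.
    """
    definitions = _resolve(score_names)
    comp_def = get_definition(comparator)
    if comp_def.name not in [d.name for d in definitions]:
        raise ValueError(f"comparator {comparator!r} not among requested scores")
    outcomes = cohort.outcomes()
    n = len(cohort)
    n_can = sum(1 for v in outcomes.values() if v == CAN)
    if n_can == 0 or n_can == n:
        raise stats.StatsError(
            "single-outcome-class cohort: relative risk, c-statistic and NRI are undefined"
        )

    strata: dict[str, dict[str, str]] = {}
    scores_by_def: dict[str, list] = {}
    tables: dict[str, stats.TwoByTwo] = {}
    stratification = []
    performance = []
    resource = [{
        "score": "none (scope all)",
        **_est_dict(stats.nns_without_score(n, n_can, level)),
    }]

    for d in definitions:
        scored, _summary = apply_score(cohort, d)
        scores_by_def[d.name] = scored
        strata[d.name] = {s.subject_id: s.stratum for s in scored}
        t = stats.make_two_by_two(scored, outcomes)
        tables[d.name] = t
        det = stats.detection_rates(t, level)
        rr = stats.relative_risk(t, level)
        chi2, p = stats.pearson_chi2(t)
        stratification.append({
            "score": d.name,
            "n_high": t.n_high, "n_non_high": t.n_non_high,
            "high_risk_rate": _est_dict(stats.high_risk_rate(t, level=level)),
            "can_high": t.a, "can_non_high": t.c,
            "detection_high": _est_dict(det[HIGH]),
            "detection_non_high": _est_dict(det[NON_HIGH]),
            "rr": _est_dict(rr), "chi2": chi2, "p": p,
        })
        diag = stats.diagnostic_metrics(t, level)
        cstat = stats.c_statistic(
            [s.score for s in scored],
            [outcomes[s.subject_id] == CAN for s in scored],
            level,
        )
        performance.append({
            "score": d.name,
            "c_statistic": _est_dict(cstat),
            **{k: _est_dict(v) for k, v in diag.items()},
        })
        resource.append({"score": d.name, **_est_dict(stats.resource_load(t, level))})

    reclassification = []
    for d in definitions:
        if d.name == comp_def.name:
            continue
        rt = stats.build_reclass_table(
            strata[comp_def.name], strata[d.name], outcomes,
            comparator=comp_def.name, new_score=d.name,
        )
        res = stats.nri(rt, level)
        reclassification.append({
            "score": d.name, "comparator": comp_def.name,
            "cells": {
                k: getattr(rt, k) for k in (
                    "e_stay_high", "e_up", "e_down", "e_stay_non",
                    "ne_stay_high", "ne_up", "ne_down", "ne_stay_non",
                )
            },
            "reclassified_pct": rt.reclassified_percent(),
            "nri_pct": _est_dict(res.estimate),
            "z": res.z, "p": res.p,
        })

    bundle = {
        "meta": {
            "n": n, "n_can": n_can,
            "prevalence_pct": 100.0 * n_can / n,
            "scores": [d.name for d in definitions],
            "comparator": comp_def.name,
            "confidence_level": level,
            "methods": {
                "proportion_ci": "Clopper-Pearson exact",
                "rr_ci": "Katz log",
                "chi2": "Pearson, unadjusted, 1 df",
                "c_statistic_ci": "DeLong",
                "nri": "binary NRI, Pencina asymptotic z",
                "nns": "half-up rounding; inverse Clopper-Pearson CI",
            },
            **(dict(meta) if meta else {}),
        },
        "characteristics": characteristics_table(cohort).to_dict(orient="records"),
        "stratification": stratification,
        "performance": performance,
        "reclassification": reclassification,
        "resource_load": resource,
    }
    return bundle


def _est_dict(e: stats.EstimateWithCI) -> dict:
    return {"point": e.point, "lo": e.lo, "hi": e.hi,
            "level": e.level, "method": e.method}


def bundle_to_json(bundle: dict) -> str:
    """Deterministic serialisation (sorted keys, fixed layout)."""
    return json.dumps(_finite(bundle), sort_keys=True, indent=2, allow_nan=False)


def _finite(obj):
    # JSON has no NaN/inf; encode them as strings so output stays parseable.
    if isinstance(obj, dict):
        return {k: _finite(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_finite(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj


def render_text(bundle: dict) -> str:
    """Aligned plain-text tables mirroring the published layout."""
    out: list[str] = []
    meta = bundle["meta"]
    out.append(
        f"Validation report: n = {meta['n']}, CAN = {meta['n_can']} "
        f"({meta['prevalence_pct']:.2f}%), comparator = {meta['comparator']}"
    )
    out.append("Methods: " + "; ".join(f"{k}={v}" for k, v in sorted(meta["methods"].items())))

    out.append("\n== Cohort characteristics ==")
    ch = pd.DataFrame(bundle["characteristics"])
    ch["pct"] = ch["pct"].map(lambda v: f"{v:.2f}")
    out.append(ch.to_string(index=False))

    out.append("\n== Risk stratification and CAN detection ==")
    rows = []
    for r in bundle["stratification"]:
        rows.append({
            "score": r["score"],
            "high N (%)": f"{r['n_high']} ({r['high_risk_rate']['point']:.2f})",
            "high CAN (%)": f"{r['can_high']} ({r['detection_high']['point']:.2f})",
            "non-high N": r["n_non_high"],
            "non-high CAN (%)": f"{r['can_non_high']} ({r['detection_non_high']['point']:.2f})",
            "RR (95% CI)": _fmt_ci(r["rr"]),
            "P": _fmt_p(r["p"]),
        })
    out.append(pd.DataFrame(rows).to_string(index=False))

    out.append("\n== Performance characteristics ==")
    rows = []
    for r in bundle["performance"]:
        rows.append({
            "score": r["score"],
            "c-statistic (95% CI)": _fmt_ci(r["c_statistic"], nd=2, scale=1),
            "sensitivity": _fmt_ci(r["sensitivity"]),
            "specificity": _fmt_ci(r["specificity"]),
            "PPV": _fmt_ci(r["ppv"]),
            "NPV": _fmt_ci(r["npv"]),
        })
    out.append(pd.DataFrame(rows).to_string(index=False))

    if bundle["reclassification"]:
        out.append("\n== Reclassification vs comparator ==")
        rows = []
        for r in bundle["reclassification"]:
            rows.append({
                "score": r["score"],
                "events up/down": f"{r['cells']['e_up']}/{r['cells']['e_down']}",
                "non-events up/down": f"{r['cells']['ne_up']}/{r['cells']['ne_down']}",
                "NRI % (95% CI)": _fmt_ci(r["nri_pct"]),
                "P": _fmt_p(r["p"]),
            })
        out.append(pd.DataFrame(rows).to_string(index=False))

    out.append("\n== Colonoscopy resource load (NNS) ==")
    rows = [{"score": r["score"], "NNS (95% CI)":
             f"{r['point']:.0f} ({r['lo']:.0f}-{r['hi']:.0f})"}
            for r in bundle["resource_load"]]
    out.append(pd.DataFrame(rows).to_string(index=False))
    return "\n".join(out) + "\n"


def _fmt_ci(d: dict, nd: int = 2, scale: float = 1.0) -> str:
    return f"{d['point']*scale:.{nd}f} ({d['lo']*scale:.{nd}f}-{d['hi']*scale:.{nd}f})"


#: Structural schema for the report bundle (subset of JSON Schema).
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["meta", "characteristics", "stratification",
                 "performance", "reclassification", "resource_load"],
    "properties": {
        "meta": {
            "type": "object",
            "required": ["n", "n_can", "prevalence_pct", "scores",
                         "comparator", "confidence_level", "methods"],
        },
        "characteristics": {"type": "array", "items": {
            "type": "object", "required": ["characteristic", "category", "n", "pct"]}},
        "stratification": {"type": "array", "items": {
            "type": "object",
            "required": ["score", "n_high", "n_non_high", "high_risk_rate",
                         "can_high", "can_non_high", "detection_high",
                         "detection_non_high", "rr", "chi2", "p"]}},
        "performance": {"type": "array", "items": {
            "type": "object",
            "required": ["score", "c_statistic", "sensitivity",
                         "specificity", "ppv", "npv"]}},
        "reclassification": {"type": "array", "items": {
            "type": "object",
            "required": ["score", "comparator", "cells",
                         "reclassified_pct", "nri_pct", "z", "p"]}},
        "resource_load": {"type": "array", "items": {
            "type": "object", "required": ["score", "point", "lo", "hi"]}},
    },
}


def conforms_to_schema(obj, schema: dict, path: str = "$") -> list[str]:
    """Minimal structural validator for :data:`REPORT_SCHEMA`.

    Supports the subset used there: type object/array, required, properties,
    items.  Returns a list of violation messages (empty = conforming).
    """
    errors: list[str] = []
    t = schema.get("type")
    if t == "object":
        if not isinstance(obj, dict):
            return [f"{path}: expected object"]
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(conforms_to_schema(obj[key], sub, f"{path}.{key}"))
    elif t == "array":
        if not isinstance(obj, list):
            return [f"{path}: expected array"]
        items = schema.get("items")
        if items:
            for i, v in enumerate(obj):
                errors.extend(conforms_to_schema(v, items, f"{path}[{i}]"))
    return errors
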