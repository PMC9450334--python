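"""Recompute the published validation statistics from the published counts.

The validation study published its per-score stratum x outcome counts and
reclassification cells; those counts fully determine the detection rates,
relative risks, diagnostic accuracy with exact CIs, NRIs and colonoscopy
resource load.  This driver feeds them through the library and prints each
recomputed value next to nothing but count inputs — every number below is
computed at run time.

Run from the repository root:  python analysis/03_published_reproduction.py
"""

import json
from pathlib import Path

from crcscreen.datasets import (
    STUDY_CAN, STUDY_N, STUDY_RECLASS_VS_APCS, STUDY_TWO_BY_TWO,
)
from crcscreen.stats import (
    detection_rates, diagnostic_metrics, format_nri_ci_published_style,
    high_risk_rate, nns_without_score, nri, pearson_chi2, relative_risk,
    resource_load, round_half_up,
)

ROOT = Path(__file__).resolve().parents[1]


def fmt(e, nd=2):
    return f"{round_half_up(e.point, nd):.{nd}f} ({round_half_up(e.lo, nd):.{nd}f}-{round_half_up(e.hi, nd):.{nd}f})"


def main() -> None:
    out = {}
    print(f"cohort: N = {STUDY_N}, CAN = {STUDY_CAN} "
          f"({100 * STUDY_CAN / STUDY_N:.2f}%)\n")

    print("== stratification, detection and relative risk ==")
    for name, t in STUDY_TWO_BY_TWO.items():
        det = detection_rates(t)
        rr = relative_risk(t)
        chi2, p = pearson_chi2(t)
        row = {
            "high_risk_rate": fmt(high_risk_rate(t)),
            "detection_high": fmt(det["high"]),
            "detection_non_high": fmt(det["non_high"]),
            "rr": fmt(rr),
            "p": "< 0.001" if p < 0.001 else f"{p:.3f}",
        }
        out[name] = row
        print(f"{name:14s} high {t.n_high:4d} ({row['high_risk_rate']}%)  "
              f"det {row['detection_high']}% vs {row['detection_non_high']}%  "
              f"RR {row['rr']}  P {row['p']}")

    print("\n== diagnostic accuracy ==")
    for name, t in STUDY_TWO_BY_TWO.items():
        m = diagnostic_metrics(t)
        out[name]["accuracy"] = {k: fmt(v) for k, v in m.items()}
        print(f"{name:14s} sens {fmt(m['sensitivity'])}  spec {fmt(m['specificity'])}  "
              f"PPV {fmt(m['ppv'])}  NPV {fmt(m['npv'])}")

    print("\n== reclassification vs APCS ==")
    for name, rt in STUDY_RECLASS_VS_APCS.items():
        res = nri(rt)
        lo, hi = format_nri_ci_published_style(res)
        out[name]["nri"] = {
            "pct": round_half_up(res.estimate.point, 2),
            "ci_quoted": [lo, hi], "p": round_half_up(res.p, 3),
        }
        print(f"{name:14s} NRI {round_half_up(res.estimate.point, 2):6.2f}% "
              f"({lo:.2f} to {hi:.2f}%)  P {res.p:.3f}")

    print("\n== colonoscopy resource load ==")
    base = nns_without_score(STUDY_N, STUDY_CAN)
    print(f"{'no score':14s} NNS {base.point:.0f} ({base.lo:.0f}-{base.hi:.0f})")
    out["no_score_nns"] = base.point
    for name, t in STUDY_TWO_BY_TWO.items():
        e = resource_load(t)
        out[name]["nns"] = e.point
        print(f"{name:14s} NNS {e.point:.0f} ({e.lo:.0f}-{e.hi:.0f})")

    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "published_reproduction.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )
    print("\nwrote results/published_reproduction.json")


if __name__ == "__main__":
    main()
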