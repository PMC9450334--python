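"""Draw the synthetic screening cohort used by the downstream analyses.

Generates a cohort at the validation study's size (n = 1804) plus a larger
one (n = 20000) for stable rate estimates, both under the study-condition
marginals with the CAN prevalence calibrated to 6.21%.  The cohort CSVs are
bulky intermediates and go under scratch/; the generator reports (realized
marginals, calibrated intercept, seed) go under results/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from crcscreen.cohort import write_cohort
from crcscreen.simulate import default_config, expected_prevalence, generate

SEED = 20140801
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    for n, tag in ((1804, "studysize"), (20000, "large")):
        cfg = default_config(n=n, seed=SEED)
        cohort, report = generate(cfg)
        csv_path = ROOT / "scratch" / f"synthetic_cohort_{tag}.csv"
        write_cohort(cohort, csv_path)
        (ROOT / "results" / f"generator_report_{tag}.json").write_text(
            report.to_json() + "\n"
        )
        print(
            f"n={n:>6}: wrote {csv_path.name}; intercept {report.intercept:.4f}, "
            f"realized prevalence {100 * report.realized['prevalence']:.2f}% "
            f"(target {100 * cfg.target_prevalence:.2f}%, grid expectation "
            f"{100 * expected_prevalence(cfg, report.intercept):.4f}%)"
        )


if __name__ == "__main__":
    main()
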