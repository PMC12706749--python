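"""Simulate the synthetic city and write the study tables.

Generates the full study — fixed ambient network, rolling one-week
school deployments with biased continuous monitors and unbiased filter
samples, minute-level schoolyard sound, covariates, meteorology and
annoyance surveys — and writes every compact table under
``results/data/``.  The minute-level series are regenerated on demand by
the later drivers (the config plus seed reproduces them bit for bit),
so only summaries go to disk here.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, default_config, parser

from schoolenv import generate_study
from schoolenv.synthetic import config_to_file


def main() -> None:
    args = parser(__doc__).parse_args()
    cfg = default_config(args.seed)
    bundle, truth = generate_study(cfg)

    DATA.mkdir(parents=True, exist_ok=True)
    config_to_file(cfg, DATA / "config.txt")
    frames = bundle.to_frames()
    for name in ("network", "filters", "covariates", "meteorology", "surveys"):
        frames[name].to_csv(DATA / f"{name}.csv", index=False)
    truth.to_frame().to_csv(DATA / "ground_truth.csv", index=False)

    field = truth.weekly_field
    print(f"Simulated {cfg.n_schools} schools over {cfg.weeks} weeks "
          f"({len(cfg.harmattan_weeks)} Harmattan), seed={cfg.seed}.")
    print(f"Weekly temporal field spans {min(field.values()):.2f}–{max(field.values()):.2f} "
          f"(mean {sum(field.values())/len(field):.3f}).")
    print(f"True annual PM2.5 across schools: "
          f"{min(truth.school_true_annual_pm.values()):.1f}–"
          f"{max(truth.school_true_annual_pm.values()):.1f} µg/m³.")
    print(f"Wrote study tables to {DATA}/ (ground_truth.csv is for evaluation only).")


if __name__ == "__main__":
    main()
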