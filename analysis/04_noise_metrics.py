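"""School-hours noise levels, weekly Leq, break excess and intermittency.

Computes L_day(school) (weekday 07:00–15:00 Leq with break windows
excluded), the whole-week Leq_wk, the mean break-vs-class Leq
difference, and the intermittency ratio (share of sound energy from
minutes more than 3 dBA above the day's Leq), then compares levels
against the Ghana EPA 55 dBA standard for educational facilities.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_study, parser

import numpy as np

from schoolenv import break_delta, ghana_epa_exceeds
from schoolenv.pipeline import noise_metrics


def main() -> None:
    args = parser(__doc__).parse_args()
    bundle, _truth = load_study(args.seed)
    table = noise_metrics(bundle)
    table["exceeds_ghana_epa"] = [ghana_epa_exceeds(v) for v in table["l_day_school"]]

    deltas = [break_delta(dep.sound) for dep in bundle.deployments.values()]

    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "noise_metrics.csv", index=False)

    q = table["l_day_school"].quantile([0.25, 0.5, 0.75])
    print(f"L_day(school) median (IQR): {q[0.5]:.1f} ({q[0.25]:.1f}–{q[0.75]:.1f}) dBA; "
          f"range {table.l_day_school.min():.1f}–{table.l_day_school.max():.1f}.")
    print(f"Leq_wk median: {table.leq_wk.median():.1f} dBA; "
          f"IR median (IQR): {table.ir.median():.1f}% "
          f"({table.ir.quantile(0.25):.1f}–{table.ir.quantile(0.75):.1f}%).")
    print(f"{100 * table.exceeds_ghana_epa.mean():.0f}% of schools exceed the 55 dBA standard.")
    print(f"Break periods average {np.mean(deltas):+.2f} dBA vs class hours.")
    print(f"Wrote {RESULTS/'noise_metrics.csv'}.")


if __name__ == "__main__":
    main()
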