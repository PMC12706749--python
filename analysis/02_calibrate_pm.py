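"""Gravimetric concentrations, QC and seasonal correction factors.

Quality-controls every filter sample (≥75% runtime, flow within 10% of
1 l/min), computes gravimetric PM2.5 and BC absorbance for valid
filters, derives per-school collocation correction factors for the
continuous monitors and pools them into season-specific means — the
factors later used to correct schools whose filter failed QC.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_study, parser

from schoolenv.pipeline import calibrate


def main() -> None:
    args = parser(__doc__).parse_args()
    bundle, _truth = load_study(args.seed)
    calibration, seasonal_cfs = calibrate(bundle)

    RESULTS.mkdir(parents=True, exist_ok=True)
    calibration.to_csv(RESULTS / "calibration.csv", index=False)

    n_invalid = int((~calibration["qc_valid"]).sum())
    print(f"{len(calibration)} filter samples; {n_invalid} failed QC "
          f"({', '.join(calibration.loc[~calibration.qc_valid, 'qc_reasons'].unique()) or 'none'}).")
    for season, cf in sorted(seasonal_cfs.items()):
        print(f"Season {season}: mean CF = {cf.value:.3f} over {cf.n_collocations} collocations.")
    print(f"Wrote {RESULTS/'calibration.csv'}.")


if __name__ == "__main__":
    main()
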