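"""Screen all 20 model parameters for their influence on methane output.

Central-difference relative sensitivities (±50%) of the reference bottle's
final methane volume, with the one-sided +100% variant alongside, sorted by
magnitude and classified against the 0.1 threshold.
"""

import argparse
from pathlib import Path

from lcfad import screen
from lcfad.params import ESTIMATED_PARAMETERS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--threshold", type=float, default=0.1)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = screen(threshold=args.threshold)
    table.to_csv(args.outdir / "sensitivity_screen.csv", index=False)
    print(table.round(5).to_string(index=False))

    high = set(table[table.classification == "high"].parameter)
    print(f"\nhigh-sensitivity set (|delta| > {args.threshold}): {sorted(high)}")
    missing = set(ESTIMATED_PARAMETERS) - high
    if missing:
        print("note: at the reference parameter set the day-20 output is "
              "dominated by the upstream chain kinetics; these calibration "
              f"targets screen low here: {sorted(missing)}")


if __name__ == "__main__":
    main()
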