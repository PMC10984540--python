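"""Paired-error statistics over the cross-validation results of 02.

Reads the comparison families written by 02_evaluate.py: all pairwise
dataset comparisons per attribute (Wilcoxon signed-rank on per-subject
absolute errors, BH-corrected at q = 0.05) and the crystallized-vs-fluid
paired comparison within each dataset.  Prints which differences survive
correction.  Expected in this stated world: dataset conditions are
exchangeable (no rejections), while crystallized intelligence (strong
planted signal) beats fluid (weak signal) in every dataset.
"""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    if not OUT.exists():
        raise SystemExit("run analysis/02_evaluate.py first")

    print("=== pairwise dataset comparisons (BH q = 0.05) ===")
    for path in sorted(OUT.glob("comparisons_*.csv")):
        fam = pd.read_csv(path)
        label = path.stem.removeprefix("comparisons_")
        n_rej = int(fam.rejected.sum())
        min_p = fam.raw_p.min()
        print(f"{label:>22}: {n_rej}/{len(fam)} rejected "
              f"(smallest raw p = {min_p:.4f})")

    print("\n=== crystallized vs fluid intelligence, per dataset ===")
    for path in sorted(OUT.glob("feature_pair_*.csv")):
        fam = pd.read_csv(path)
        label = path.stem.removeprefix("feature_pair_")
        print(f"--- {label} ---")
        cols = ["condition_a", "condition_b", "n_effective", "raw_p",
                "adjusted_p", "rejected"]
        print(fam[cols].round(4).to_string(index=False))
        print(f"{int(fam.rejected.sum())}/{len(fam)} datasets significant after BH")


if __name__ == "__main__":
    main()
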