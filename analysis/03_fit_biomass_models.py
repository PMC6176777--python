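#!/usr/bin/env python
"""Fit the exponential biomass models and cross-validate them.

Screens candidate predictors for collinearity (|r| < 0.69), fits the six
simple and ten multiple exponential regressions for fresh and dry biomass
on a seeded 4:1 train/test split, reports 10-fold cross-validation RMSE
(with the fold-RMSE spread) and held-out-set RMSE / Pearson r, and writes
the report tables under results/report/.
"""

from pathlib import Path

import pandas as pd

from canophen.pipeline import write_model_report

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    traits_path = ROOT / "scratch" / "traits.csv"
    truth_path = ROOT / "scratch" / "scene" / "truth.csv"
    if not traits_path.exists() or not truth_path.exists():
        raise SystemExit("run analysis/01 and 02 first")
    traits = pd.read_csv(traits_path)
    truth = pd.read_csv(truth_path)
    written = write_model_report(ROOT / "results" / "report", traits, truth,
                                 seed=SEED)
    models = pd.read_csv(written["models"])
    fitted = models[~models["skipped"]]
    print(f"{len(fitted)} models fitted, {int(models['skipped'].sum())} "
          f"skipped by the collinearity screen")
    for resp, sub in fitted.groupby("response"):
        best = sub.loc[sub["test_r"].idxmax()]
        print(f"  {resp}: best test r = {best['test_r']:.2f} "
              f"({best['predictors']}), {best['formula']}")


if __name__ == "__main__":
    main()
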