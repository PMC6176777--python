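"""End-to-end orchestration shared by the CLI and the analysis scripts."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as M
from . import reference

__all__ = [
    "CANDIDATE_PREDICTORS",
    "predictor_table",
    "run_biomass_models",
    "run_treatment_ttests",
    "run_lab_correlations",
    "write_model_report",
]

log = logging.getLogger(__name__)

#: Candidate biomass predictors in reporting order; PH is mapped from the
#: chosen height percentile column.
CANDIDATE_PREDICTORS = ("PH", "CC", "NDVI", "NDRE", "RDVI", "RGBVI")

_TRAIT_COLUMNS = {
    "CC": "cc",
    "NDVI": "ndvi",
    "NDRE": "ndre",
    "RDVI": "rdvi",
    "RGBVI": "rgbvi",
}


def predictor_table(traits: pd.DataFrame, height_percentile: int = 90) -> pd.DataFrame:
    """Traits table reshaped to the canonical predictor columns (plus plot_id)."""
    out = pd.DataFrame({"plot_id": traits["plot_id"]})
    out["PH"] = traits[f"ph{height_percentile}"]
    for pred, col in _TRAIT_COLUMNS.items():
        out[pred] = traits[col]
    return out


def run_biomass_models(
    traits: pd.DataFrame,
    truth: pd.DataFrame,
    response: str,
    predictor_sets: list[tuple[str, ...]] | None = None,
    height_percentile: int = 90,
    k: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    admissibility_threshold: float = reference.ADMISSIBILITY_THRESHOLD,
) -> pd.DataFrame:
    """Fit SER/MER exponential models for one biomass response.

    Merges traits with ground truth on plot_id, screens each requested
    predictor set against the sample correlation matrix (sets with a pair at
    or above the admissibility threshold are skipped and logged), then for
    each admissible set: fits on a seeded 4:1 training split, cross-validates
    with k folds, and evaluates RMSE and Pearson r on the held-out test set.
    """
    if predictor_sets is None:
        predictor_sets = [(p,) for p in CANDIDATE_PREDICTORS] + list(
            reference.MER_PREDICTOR_SETS
        )
    if not predictor_sets:
        raise ValueError("no predictor sets requested")
    X = predictor_table(traits, height_percentile)
    data = X.merge(truth[["plot_id", response]], on="plot_id").dropna()
    n = len(data)
    corr = M.correlation_matrix(data, columns=list(CANDIDATE_PREDICTORS),
                                threshold=admissibility_threshold)
    train_idx, test_idx = M.train_test_split(n, test_fraction, seed=seed)
    rows = []
    for preds in predictor_sets:
        preds = tuple(preds)
        if len(preds) > 1:
            _, rejected = M.admissible_predictor_sets(
                corr, admissibility_threshold, extra_sets=[preds]
            )
            hit = [rej for rej in rejected if rej[0] == preds]
            if hit:
                log.warning("skipping %s: %s", "+".join(preds), hit[0][1])
                rows.append(
                    {"kind": "MER", "predictors": "+".join(preds), "skipped": True,
                     "reason": hit[0][1]}
                )
                continue
        sub = data.iloc[train_idx]
        model = M.fit_exponential(sub, sub[response], predictors=list(preds),
                                  response=response)
        cv = M.kfold_cv(sub, sub[response], k=min(k, len(sub)), seed=seed,
                        predictors=list(preds), response=response)
        test = M.evaluate_on_test(
            model, data.iloc[test_idx], data.iloc[test_idx][response]
        )
        row = {
            "kind": "SER" if len(preds) == 1 else "MER",
            "predictors": "+".join(preds),
            "a": model.a,
            "skipped": False,
            "reason": "",
            "cv_rmse": cv.rmse,
            "cv_std": cv.std,
            "test_rmse": test.rmse,
            "test_r": test.r,
            "n_train": len(train_idx),
            "n_test": len(test_idx),
            "formula": model.formula(),
        }
        for name, bj in zip(preds, model.b):
            row[f"b_{name}"] = bj
        rows.append(row)
    return pd.DataFrame(rows)


def run_treatment_ttests(
    traits: pd.DataFrame, vi_columns=("ci_green", "ci_rededge", "ndre")
) -> pd.DataFrame:
    """Student's t-tests of selected VIs between the two nitrogen treatments."""
    rows = []
    for vi in vi_columns:
        sub = traits[["treatment", vi]].dropna()
        res = M.treatment_ttest(sub[vi], sub["treatment"])
        rows.append(
            {"vi": vi, "t": res.t, "p_value": res.p_value,
             "mean_1": res.group_means[0], "mean_2": res.group_means[1],
             "n_1": res.group_sizes[0], "n_2": res.group_sizes[1]}
        )
    return pd.DataFrame(rows)


def run_lab_correlations(
    traits: pd.DataFrame,
    lab: pd.DataFrame,
    vi_columns=("ci_green", "ci_rededge", "gndvi", "ndvi", "ndre"),
    lab_columns=("chlorophyll", "leaf_N_pct"),
    on=("plot_id",),
) -> pd.DataFrame:
    """Pearson correlations of plot-mean VIs with lab-measured leaf traits."""
    return M.correlate_vi_with_lab(traits, lab, vi_columns, lab_columns, on=list(on))


def write_model_report(
    out_dir,
    traits: pd.DataFrame,
    truth: pd.DataFrame,
    responses=("fresh_biomass_kg", "dry_biomass_kg"),
    height_percentile: int = 90,
    k: int = 10,
    seed: int = 0,
    predictor_sets=None,
) -> dict[str, Path]:
    """Run the full modelling stage and write the report tables as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    model_frames = []
    for response in responses:
        df = run_biomass_models(
            traits, truth, response, predictor_sets=predictor_sets,
            height_percentile=height_percentile, k=k, seed=seed,
        )
        df.insert(0, "response", response)
        model_frames.append(df)
    all_models = pd.concat(model_frames, ignore_index=True)
    written["models"] = out / "models.csv"
    all_models.to_csv(written["models"], index=False)
    fitted = all_models[~all_models["skipped"]]
    written["cv"] = out / "cv.csv"
    fitted[["response", "kind", "predictors", "cv_rmse", "cv_std"]].to_csv(
        written["cv"], index=False
    )
    written["test"] = out / "test.csv"
    fitted[["response", "kind", "predictors", "test_rmse", "test_r"]].to_csv(
        written["test"], index=False
    )
    merged = traits.merge(
        truth[[c for c in ("plot_id", "chlorophyll", "leaf_N_pct") if c in truth]],
        on="plot_id", how="left",
    )
    if "treatment" in traits:
        written["ttests"] = out / "ttests.csv"
        run_treatment_ttests(traits).to_csv(written["ttests"], index=False)
    lab_cols = [c for c in ("chlorophyll", "leaf_N_pct") if c in merged]
    if lab_cols:
        written["vi_lab_corr"] = out / "vi_lab_corr.csv"
        run_lab_correlations(
            traits, truth[["plot_id", *lab_cols]], lab_columns=lab_cols
        ).to_csv(written["vi_lab_corr"], index=False)
    return written
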