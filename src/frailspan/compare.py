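"""Head-to-head comparison of the three 95PLL predictors.

Builds, on one cohort and one grouped train/test split, the three predictive
endpoints whose ranking is the study's qualitative headline:

* **TxW** — random-intercept logistic model with the TxW pass/fail flag as
  the only fixed effect; fixed-effects-only probabilities on test mice.
* **TxW+FgI** — same model plus the continuous FgI score.
* **ML-FgI** — the stacked ensemble over feature recipes.

All three are evaluated by ROC-AUC on the same held-out mice; TxW-based
models use the subset of rows with sufficient TxW history (the rule needs a
13-week look-back window).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .endpoints import label_assessments
from .ensemble import (
    assemble_rows,
    complete_rows,
    evaluate as evaluate_ensemble,
    split_grouped,
    stack,
    tune_candidates,
)
from .fgi import default_catalog, score_assessments
from .glmm import fit_glmm, predict_fixed, roc_auc
from .synthetic import CohortConfig, generate_cohort
from .txw import txw_status_table

__all__ = ["compare_predictors", "REDUCED_GRIDS"]

#: Compact hyperparameter grids for desk-scale runs.
REDUCED_GRIDS = {
    "RLR": [{"C": c, "l1_ratio": 0} for c in (0.01, 0.1, 1.0, 10.0)],
    "RF": [
        {"n_estimators": 100, "min_samples_leaf": 10, "max_features": "sqrt"}
    ],
    "XGB": [
        {"n_estimators": 150, "max_depth": d, "learning_rate": 0.1, "subsample": 0.8}
        for d in (2, 4)
    ],
    "SVM": [{"C": c, "gamma": "scale"} for c in (0.1, 1.0)],
}


def compare_predictors(
    seed: int,
    n_mice_per_group: int = 60,
    config: CohortConfig | None = None,
    learners: tuple[str, ...] = ("RLR", "RF", "XGB"),
    recipes: tuple[str, ...] = ("M0", "M1", "M2", "M3"),
    grids: dict | None = None,
) -> dict:
    """Generate a DO-style cohort and score the three predictors on it.

    Returns a dict with test AUCs (``auc_ensemble``, ``auc_txw_fgi``,
    ``auc_txw``), the ensemble's threshold report, and bookkeeping counts.
    """
    catalog = default_catalog()
    config = config or CohortConfig(
        n_mice_per_group=n_mice_per_group, strains=("DO",), seed=seed
    )
    mice, assessments, _ = generate_cohort(config)
    fgi = score_assessments(assessments, catalog)
    labels = label_assessments(assessments, mice)
    statuses = txw_status_table(assessments)

    rows = assemble_rows(assessments, mice, labels, catalog)
    rows = complete_rows(rows, max(recipes), catalog)
    used_mice = mice[mice["mouse_id"].isin(rows["mouse_id"])]

    master = np.random.SeedSequence(seed)
    s_split, s_tune, s_stack = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(3)
    )
    plan = split_grouped(used_mice, seed=s_split)
    train_rows = rows[~rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
    test_rows = rows[rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)

    candidates = tune_candidates(
        train_rows, plan, learners=learners, recipes=recipes,
        grids=grids or REDUCED_GRIDS, catalog=catalog, seed=s_tune,
    )
    model = stack(candidates, train_rows, plan, catalog=catalog, seed=s_stack)
    report = evaluate_ensemble(model, test_rows)

    # GLMM endpoints on rows with sufficient TxW history
    glmm_rows = (
        statuses.merge(labels, on=["mouse_id", "date"])
        .merge(fgi[["mouse_id", "date", "fgi_score"]], on=["mouse_id", "date"])
    )
    glmm_rows = glmm_rows[glmm_rows["flag"] != "insufficient"].copy()
    glmm_rows["txw_fail"] = (glmm_rows["flag"] == "fail").astype(float)
    glmm_train = glmm_rows[~glmm_rows["mouse_id"].isin(plan.test_mouse_ids)]
    glmm_test = glmm_rows[glmm_rows["mouse_id"].isin(plan.test_mouse_ids)]

    fit_txw = fit_glmm(glmm_train, fixed_terms=("txw_fail",))
    fit_both = fit_glmm(glmm_train, fixed_terms=("txw_fail", "fgi_score"))
    _, auc_txw = roc_auc(predict_fixed(fit_txw, glmm_test), glmm_test["is_95pll"])
    _, auc_both = roc_auc(predict_fixed(fit_both, glmm_test), glmm_test["is_95pll"])

    return {
        "auc_ensemble": report["auc_roc"],
        "auc_pr_ensemble": report["auc_pr"],
        "auc_txw_fgi": auc_both,
        "auc_txw": auc_txw,
        "thresholds": report["thresholds"],
        "model": model,
        "n_mice": len(used_mice),
        "n_train_rows": len(train_rows),
        "n_test_rows": len(test_rows),
        "n_glmm_test_rows": len(glmm_test),
        "glmm_fits": {"txw": fit_txw, "txw_fgi": fit_both},
    }
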