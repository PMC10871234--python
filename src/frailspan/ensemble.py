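"""Stacked-ensemble classifier for the 95PLL terminal-decline endpoint.

Pipeline, mirroring the study design it re-implements:

1. **Feature recipes** M0-M3 (nested): M0 = age + diet (and sex/strain when
   present); M1 adds current weight/temperature and their 30-day rolling
   percent change; M2 adds the 30 ordinal deficit items rescaled to integer
   scores ({0,1} -> {1,3}, {0,0.5,1} -> {1,2,3}), zero-variance-filtered and
   reduced to 5 principal components; M3 adds 30-day deficit deltas, reduced
   to 5 further components.  All continuous features are standardized; PCA
   rotations and scaling constants are learned on training rows only.
2. **Grouped splitting**: 25% of mice (not rows) held out for testing,
   stratified by diet; training mice partitioned into 5 grouped CV folds.
3. **Candidate tuning**: for each learner (RF, SVM, RLR, XGB) x recipe, up to
   25 hyperparameter configurations evaluated by grouped CV on ROC-AUC with
   racing-style early elimination; minority-class rows are up-sampled inside
   each training fold only.
4. **Stacking**: out-of-fold candidate probabilities pooled; a non-negative
   L1-regularized logistic meta-model picks members with non-zero weight;
   retained members are refit on the full training data.
5. **Evaluation**: accuracy/PPV/NPV over probability thresholds 0.5-0.9 plus
   threshold-free ROC-AUC and PR-AUC; Shapley attribution of the
   highest-weight member via an in-package permutation estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .fgi import DeficitCatalog, default_catalog

__all__ = [
    "RECIPES",
    "LEARNERS",
    "SplitPlan",
    "CandidateModel",
    "EnsembleModel",
    "assemble_rows",
    "FeatureBuilder",
    "split_grouped",
    "upsample_events",
    "tune_candidates",
    "stack",
    "evaluate",
    "permutation_shapley",
    "explain_top_member",
    "train_ensemble",
]

RECIPES = ("M0", "M1", "M2", "M3")
LEARNERS = ("RF", "SVM", "RLR", "XGB")

ROLLING_WINDOW_DAYS = 30
MIN_FOLLOWUP_DAYS = 30
PCA_COMPONENTS = 5


# ---------------------------------------------------------------------------
# raw row assembly (recipe-independent)


def assemble_rows(
    assessments: pd.DataFrame,
    mice: pd.DataFrame,
    labels: pd.DataFrame,
    catalog: DeficitCatalog | None = None,
) -> pd.DataFrame:
    """Per-assessment raw modeling rows with rolling 30-day deltas.

    Excludes mice with fewer than 30 days of observation.  The 30-day delta
    compares the current measurement to the earliest observation in the
    preceding 30 days (window ``[t-30, t)`` on the date index); rows without
    such an observation carry NaN deltas.  Deficit scores are returned on the
    integer scale (1..3) with per-item 30-day differences.
    """
    catalog = catalog or default_catalog()
    df = assessments.merge(
        mice[["mouse_id", "strain", "sex", "diet"]], on="mouse_id"
    ).merge(labels[["mouse_id", "date", "is_95pll"]], on=["mouse_id", "date"])
    df = df.sort_values(["mouse_id", "age_days"]).reset_index(drop=True)

    raw = df[catalog.names].to_numpy(dtype=float)
    # {0,0.5,1} -> {1,2,3} and {0,1} -> {1,3}: equal absent-to-severe distance
    integer = 1.0 + 2.0 * raw
    int_cols = [f"{n}__int" for n in catalog.names]
    delta_cols = [f"{n}__d30" for n in catalog.names]

    out_parts = []
    for mouse_id, sub in df.groupby("mouse_id", sort=False):
        idx = sub.index.to_numpy()
        days = pd.to_datetime(sub["date"]).astype("int64").to_numpy() // 86_400_000_000_000
        span = days[-1] - days[0]
        if span < MIN_FOLLOWUP_DAYS:
            continue
        n = len(sub)
        w = sub["weight_g"].to_numpy(dtype=float)
        t = sub["temp_C"].to_numpy(dtype=float)
        ints = integer[idx]
        wt_pct = np.full(n, np.nan)
        tp_pct = np.full(n, np.nan)
        deltas = np.full((n, len(catalog.names)), np.nan)
        for i in range(n):
            in_win = (days >= days[i] - ROLLING_WINDOW_DAYS) & (days < days[i])
            if not in_win.any():
                continue
            j = int(np.flatnonzero(in_win)[0])  # earliest in window
            if not (np.isnan(w[j]) or np.isnan(w[i])) and w[j] > 0:
                wt_pct[i] = 100.0 * (w[i] - w[j]) / w[j]
            if not (np.isnan(t[j]) or np.isnan(t[i])) and t[j] > 0:
                tp_pct[i] = 100.0 * (t[i] - t[j]) / t[j]
            deltas[i] = ints[i] - ints[j]
        part = sub[["mouse_id", "date", "age_days", "strain", "sex", "diet",
                    "weight_g", "temp_C", "is_95pll"]].copy()
        part["wt_pct30"] = wt_pct
        part["temp_pct30"] = tp_pct
        part[int_cols] = ints
        part[delta_cols] = deltas
        out_parts.append(part)
    if not out_parts:
        raise ValueError("no mouse has >= 30 days of observation")
    return pd.concat(out_parts, ignore_index=True)


def _recipe_columns(recipe: str, catalog: DeficitCatalog) -> dict[str, list[str]]:
    """Raw columns each recipe needs, by block."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}")
    cols = {
        "continuous": ["age_days"],
        "categorical": ["diet", "sex", "strain"],
        "items": [],
        "deltas": [],
    }
    if recipe >= "M1":
        cols["continuous"] += ["weight_g", "temp_C", "wt_pct30", "temp_pct30"]
    if recipe >= "M2":
        cols["items"] = [f"{n}__int" for n in catalog.names]
    if recipe >= "M3":
        cols["deltas"] = [f"{n}__d30" for n in catalog.names]
    return cols


def complete_rows(rows: pd.DataFrame, recipe: str, catalog: DeficitCatalog | None = None) -> pd.DataFrame:
    """Rows with no missing value in any column the recipe requires."""
    catalog = catalog or default_catalog()
    c = _recipe_columns(recipe, catalog)
    needed = c["continuous"] + c["items"] + c["deltas"]
    return rows.dropna(subset=needed).reset_index(drop=True)


class FeatureBuilder:
    """Recipe-aware feature matrix builder with train-only learned state.

    ``fit`` learns category levels, the zero-variance filter, PCA rotations
    (sign-pinned so each loading's largest-magnitude element is positive),
    and standardization constants; ``transform`` applies them unchanged.
    """

    def __init__(self, recipe: str, catalog: DeficitCatalog | None = None,
                 n_components: int = PCA_COMPONENTS):
        self.recipe = recipe
        self.catalog = catalog or default_catalog()
        self.n_components = n_components

    def fit(self, rows: pd.DataFrame) -> "FeatureBuilder":
        c = _recipe_columns(self.recipe, self.catalog)
        self.cat_levels_ = {
            col: sorted(rows[col].astype(str).unique()) for col in c["categorical"]
        }
        self.pca_items_, self.item_cols_ = self._fit_pca(rows, c["items"], "pc_item")
        self.pca_deltas_, self.delta_cols_ = self._fit_pca(rows, c["deltas"], "pc_delta")
        raw = self._raw_matrix(rows)
        self.feature_names_ = raw.columns.tolist()
        x = raw.to_numpy(dtype=float)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        # one-hot indicator columns keep their 0/1 coding
        is_indicator = np.array([n.startswith("ind_") for n in self.feature_names_])
        self.mean_[is_indicator] = 0.0
        self.sd_[is_indicator] = 1.0
        return self

    def _fit_pca(self, rows, cols, prefix):
        if not cols:
            return None, []
        x = rows[cols].to_numpy(dtype=float)
        keep = x.std(axis=0, ddof=0) > 0  # zero-variance filter
        kept_cols = [c for c, k in zip(cols, keep) if k]
        if not kept_cols:
            return None, []
        k = min(self.n_components, len(kept_cols), len(rows))
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(x[:, keep])
        # pin component signs: largest-|loading| element positive
        for i in range(k):
            j = int(np.argmax(np.abs(pca.components_[i])))
            if pca.components_[i, j] < 0:
                pca.components_[i] *= -1.0
        return (pca, kept_cols), [f"{prefix}{i+1}" for i in range(k)]

    def _raw_matrix(self, rows: pd.DataFrame) -> pd.DataFrame:
        c = _recipe_columns(self.recipe, self.catalog)
        blocks = [rows[c["continuous"]].reset_index(drop=True).astype(float)]
        for col, levels in self.cat_levels_.items():
            if len(levels) < 2:
                continue  # constant category carries no information
            vals = rows[col].astype(str).to_numpy()
            ind = pd.DataFrame(
                {f"ind_{col}_{lv}": (vals == lv).astype(float) for lv in levels[1:]}
            )
            blocks.append(ind)
        for pca_state, names in ((self.pca_items_, self.item_cols_),
                                 (self.pca_deltas_, self.delta_cols_)):
            if pca_state is None:
                continue
            pca, kept_cols = pca_state
            scores = pca.transform(rows[kept_cols].to_numpy(dtype=float))
            blocks.append(pd.DataFrame(scores, columns=names))
        return pd.concat(blocks, axis=1)

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        raw = self._raw_matrix(rows)
        x = raw[self.feature_names_].to_numpy(dtype=float)
        return (x - self.mean_) / self.sd_


# ---------------------------------------------------------------------------
# grouped splitting and up-sampling


@dataclass(frozen=True)
class SplitPlan:
    test_mouse_ids: frozenset[str]
    folds: dict[str, int]  # training mouse_id -> fold in 1..n_folds
    seed: int
    n_folds: int = 5


def split_grouped(
    mice: pd.DataFrame,
    test_fraction: float = 0.25,
    stratify: str = "diet",
    seed: int = 0,
    n_folds: int = 5,
) -> SplitPlan:
    """Allocate mice (never rows) to a stratified test set and grouped CV folds.

    Per-stratum test counts follow largest-remainder rounding so the overall
    test count is exactly ``round(test_fraction * n)`` and each stratum is
    within one mouse of proportional.  Strata with fewer than 4 mice fall
    back to a pooled allocation (with a warning).
    """
    if len(mice) < 8:
        raise ValueError("need at least 8 mice to split")
    rng = np.random.default_rng(seed)
    ids = mice["mouse_id"].to_numpy()
    strata = mice[stratify].astype(str).to_numpy() if stratify in mice.columns else np.repeat("all", len(ids))
    labels, counts = np.unique(strata, return_counts=True)
    small = labels[counts < 4]
    if small.size:
        warnings.warn(
            f"strata with <4 mice pooled for test allocation: {small.tolist()}"
        )
        strata = np.where(np.isin(strata, small), "__pooled__", strata)
        labels = np.unique(strata)
    n_test_total = int(round(test_fraction * len(ids)))
    ideal = {g: test_fraction * (strata == g).sum() for g in labels}
    base = {g: int(np.floor(v)) for g, v in ideal.items()}
    short = n_test_total - sum(base.values())
    order = sorted(labels, key=lambda g: (-(ideal[g] - base[g]), str(g)))
    n_test = dict(base)
    for g in order[:short]:
        n_test[g] += 1
    test_ids: list[str] = []
    for g in labels:
        members = ids[strata == g]
        pick = rng.permutation(members)[: n_test[g]]
        test_ids.extend(pick.tolist())
    train_ids = [i for i in ids if i not in set(test_ids)]
    perm = rng.permutation(train_ids)
    folds = {m: (k % n_folds) + 1 for k, m in enumerate(perm)}
    return SplitPlan(
        test_mouse_ids=frozenset(test_ids), folds=folds, seed=seed, n_folds=n_folds
    )


def upsample_events(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices that resample the minority class up to the majority count.

    Returns row indices (original rows plus replicated minority rows).  Must
    only ever be applied to training rows.
    """
    y = np.asarray(y).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("up-sampling requires both classes present")
    if n1 == n0:
        return np.arange(len(y))
    minority = np.flatnonzero(y) if n1 < n0 else np.flatnonzero(~y)
    extra = rng.choice(minority, size=abs(n0 - n1), replace=True)
    return np.concatenate([np.arange(len(y)), extra])


# ---------------------------------------------------------------------------
# learners and hyperparameter grids


def make_learner(learner: str, params: dict, seed: int):
    if learner == "RF":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 300),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if learner == "SVM":
        return SVC(
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            probability=True,
            random_state=seed,
        )
    if learner == "RLR":
        return LogisticRegression(
            C=params.get("C", 1.0),
            l1_ratio=params.get("l1_ratio", 0),  # 0 = ridge, 1 = lasso
            solver="liblinear",
            max_iter=2000,
            random_state=seed,
        )
    if learner == "XGB":
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth", 4),
            learning_rate=params.get("learning_rate", 0.1),
            subsample=params.get("subsample", 1.0),
            reg_lambda=params.get("reg_lambda", 1.0),
            eval_metric="logloss",
            n_jobs=1,
            random_state=seed,
            tree_method="hist",
        )
    raise ValueError(f"unknown learner {learner!r}")


DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF": [
        {"n_estimators": n, "min_samples_leaf": l, "max_features": f}
        for n in (200, 400)
        for l in (1, 5, 20)
        for f in ("sqrt", 0.5)
    ],
    "SVM": [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01, 0.1)],
    "RLR": [
        {"C": c, "l1_ratio": lr}
        for c in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
        for lr in (0, 1)
    ],
    "XGB": [
        {"n_estimators": n, "max_depth": d, "learning_rate": lr, "subsample": s}
        for n in (100, 300)
        for d in (2, 4, 6)
        for lr in (0.05, 0.1, 0.3)
        for s in (0.7, 1.0)
    ],
}

MAX_GRID_SIZE = 25


@dataclass
class CandidateModel:
    learner: str
    recipe: str
    params: dict
    cv_auc: float
    oof_pred: np.ndarray  # aligned with the training row table
    seed: int


def _fold_cache(rows, y, fold_of_row, n_folds, recipe, catalog, seed_seq):
    """Per-fold transformed (and up-sampled) design matrices for one recipe."""
    cache = []
    for f in range(1, n_folds + 1):
        tr = fold_of_row != f
        va = fold_of_row == f
        builder = FeatureBuilder(recipe, catalog).fit(rows.loc[tr])
        x_tr = builder.transform(rows.loc[tr])
        x_va = builder.transform(rows.loc[va])
        y_tr, y_va = y[tr], y[va]
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        up = upsample_events(y_tr, rng)
        cache.append(
            {
                "x_tr": x_tr[up], "y_tr": y_tr[up],
                "x_va": x_va, "y_va": y_va,
                "va_idx": np.flatnonzero(va),
            }
        )
    return cache


def tune_candidates(
    train_rows: pd.DataFrame,
    plan: SplitPlan,
    learners: tuple[str, ...] = LEARNERS,
    recipes: tuple[str, ...] = RECIPES,
    grids: dict[str, list[dict]] | None = None,
    max_configs: int = MAX_GRID_SIZE,
    racing: bool = True,
    racing_margin: float = 0.03,
    racing_min_folds: int = 3,
    catalog: DeficitCatalog | None = None,
    seed: int = 0,
) -> list[CandidateModel]:
    """Tune each (learner, recipe) by grouped CV on ROC-AUC with racing.

    ``train_rows`` is an assembled row table restricted to training mice and
    complete for the most demanding recipe in ``recipes``.  Racing drops a
    configuration once its running mean AUC after ``racing_min_folds`` folds
    trails the best running mean by more than ``racing_margin``; survivors
    finish all folds, so the winner has full out-of-fold coverage.
    """
    catalog = catalog or default_catalog()
    grids = grids or DEFAULT_GRIDS
    if set(train_rows["mouse_id"]) & set(plan.test_mouse_ids):
        raise ValueError("training rows contain test mice")
    y = train_rows["is_95pll"].to_numpy(dtype=bool)
    fold_of_row = train_rows["mouse_id"].map(plan.folds).to_numpy()
    if np.isnan(fold_of_row.astype(float)).any():
        raise ValueError("training rows contain mice without a fold assignment")
    master = np.random.SeedSequence(seed)
    recipe_caches = {}
    rec_seq = master.spawn(len(recipes))
    for r, sq in zip(recipes, rec_seq):
        recipe_caches[r] = _fold_cache(
            train_rows, y, fold_of_row, plan.n_folds, r, catalog, sq
        )

    candidates: list[CandidateModel] = []
    pair_seqs = master.spawn(len(learners) * len(recipes))
    pi = 0
    for learner in learners:
        for recipe in recipes:
            sq = pair_seqs[pi]
            pi += 1
            rng = np.random.default_rng(sq.spawn(1)[0])
            grid = list(grids[learner])
            if len(grid) > max_configs:
                grid = [grid[i] for i in rng.choice(len(grid), max_configs, replace=False)]
            fit_seed = int(rng.integers(2**31 - 1))
            cache = recipe_caches[recipe]
            active = list(range(len(grid)))
            aucs = np.full((len(grid), plan.n_folds), np.nan)
            oof = {ci: np.full(len(train_rows), np.nan) for ci in active}
            for f in range(plan.n_folds):
                fold = cache[f]
                if len(np.unique(fold["y_va"])) < 2:
                    warnings.warn(f"fold {f+1} has one outcome class; skipped for AUC")
                    continue
                for ci in active:
                    model = make_learner(learner, grid[ci], fit_seed)
                    model.fit(fold["x_tr"], fold["y_tr"])
                    p = model.predict_proba(fold["x_va"])[:, 1]
                    oof[ci][fold["va_idx"]] = p
                    aucs[ci, f] = roc_auc_score(fold["y_va"], p)
                if racing and f + 1 >= racing_min_folds and len(active) > 1:
                    means = np.nanmean(aucs[active, : f + 1], axis=1)
                    best = np.nanmax(means)
                    active = [c for c, m in zip(active, means) if m >= best - racing_margin]
            means = np.nanmean(aucs[active], axis=1)
            winner = active[int(np.argmax(means))]
            candidates.append(
                CandidateModel(
                    learner=learner,
                    recipe=recipe,
                    params=grid[winner],
                    cv_auc=float(np.nanmax(means)),
                    oof_pred=oof[winner],
                    seed=fit_seed,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# stacking


def _nonneg_l1_logistic(P: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Logistic fit with non-negative member weights and an L1 penalty.

    With beta >= 0 the L1 penalty is linear (lam * sum(beta)), so the
    objective is smooth on the feasible region and L-BFGS-B with box bounds
    solves it exactly.  Returns (intercept, beta)."""
    n, m = P.shape

    def obj(theta):
        c0, beta = theta[0], theta[1:]
        eta = c0 + P @ beta
        nll = np.mean(np.logaddexp(0.0, np.where(y, -eta, eta)))
        grad_eta = (special.expit(eta) - y) / n
        grad = np.empty(m + 1)
        grad[0] = grad_eta.sum()
        grad[1:] = P.T @ grad_eta + lam
        return nll + lam * beta.sum(), grad

    x0 = np.zeros(m + 1)
    bounds = [(None, None)] + [(0.0, None)] * m
    res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds)
    return float(res.x[0]), res.x[1:]


@dataclass
class FittedMember:
    learner: str
    recipe: str
    params: dict
    weight: float
    builder: FeatureBuilder
    model: object
    background: np.ndarray  # training design sample for attribution


@dataclass
class EnsembleModel:
    members: list[FittedMember]
    intercept: float
    meta_lambda: float
    seed: int
    candidate_summary: pd.DataFrame = field(default=None, repr=False)

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(rows), self.intercept)
        for m in self.members:
            eta = eta + m.weight * m.model.predict_proba(m.builder.transform(rows))[:, 1]
        return special.expit(eta)


def stack(
    candidates: list[CandidateModel],
    train_rows: pd.DataFrame,
    plan: SplitPlan,
    lambdas: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1),
    catalog: DeficitCatalog | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the non-negative L1 logistic meta-model and refit retained members.

    The penalty is chosen by grouped CV (re-using the plan's folds) on
    ROC-AUC over the pooled out-of-fold table; members with non-zero weight
    are refit on all training rows (with up-sampling) to form the ensemble.
    """
    catalog = catalog or default_catalog()
    if not candidates:
        raise ValueError("no candidates to stack")
    y = train_rows["is_95pll"].to_numpy(dtype=bool)
    P = np.column_stack([c.oof_pred for c in candidates])
    ok = ~np.isnan(P).any(axis=1)
    Pk, yk = P[ok], y[ok]
    fold_of_row = train_rows["mouse_id"].map(plan.folds).to_numpy()[ok]

    cv_auc = []
    for lam in lambdas:
        scores = []
        for f in range(1, plan.n_folds + 1):
            tr, va = fold_of_row != f, fold_of_row == f
            if len(np.unique(yk[va])) < 2:
                continue
            c0, beta = _nonneg_l1_logistic(Pk[tr], yk[tr], lam)
            scores.append(roc_auc_score(yk[va], c0 + Pk[va] @ beta))
        cv_auc.append(np.mean(scores) if scores else np.nan)
    best_lam = float(lambdas[int(np.nanargmax(cv_auc))])
    c0, beta = _nonneg_l1_logistic(Pk, yk, best_lam)
    retained = [i for i in range(len(candidates)) if beta[i] > 1e-8]
    if not retained:
        raise ValueError(
            "all stacking coefficients are zero; decrease the meta-model penalty"
        )

    members = []
    for i in retained:
        c = candidates[i]
        builder = FeatureBuilder(c.recipe, catalog).fit(train_rows)
        x = builder.transform(train_rows)
        # refit randomness keyed to the candidate's identity, not its position,
        # so duplicated candidates refit identically
        rng = np.random.default_rng(np.random.SeedSequence([seed, c.seed]))
        up = upsample_events(y, rng)
        model = make_learner(c.learner, c.params, c.seed)
        model.fit(x[up], y[up])
        bg_idx = rng.choice(len(x), size=min(100, len(x)), replace=False)
        members.append(
            FittedMember(
                learner=c.learner, recipe=c.recipe, params=c.params,
                weight=float(beta[i]), builder=builder, model=model,
                background=x[bg_idx],
            )
        )
    summary = pd.DataFrame(
        [
            {"learner": c.learner, "recipe": c.recipe, "cv_auc": c.cv_auc,
             "weight": float(beta[i])}
            for i, c in enumerate(candidates)
        ]
    )
    return EnsembleModel(
        members=members, intercept=c0, meta_lambda=best_lam, seed=seed,
        candidate_summary=summary,
    )


# ---------------------------------------------------------------------------
# evaluation


THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


def evaluate(model: EnsembleModel, test_rows: pd.DataFrame) -> dict:
    """ClassifierReport: threshold metrics plus ROC-AUC and PR-AUC."""
    y = test_rows["is_95pll"].to_numpy(dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("test rows contain a single outcome class")
    p = model.predict_proba(test_rows)
    rows = []
    for thr in THRESHOLDS:
        pos = p >= thr
        tp, fp = int((pos & y).sum()), int((pos & ~y).sum())
        tn, fn = int((~pos & ~y).sum()), int((~pos & y).sum())
        rows.append(
            {
                "threshold": thr,
                "accuracy": (tp + tn) / len(y),
                "ppv": tp / (tp + fp) if tp + fp else float("nan"),
                "npv": tn / (tn + fn) if tn + fn else float("nan"),
            }
        )
    return {
        "thresholds": pd.DataFrame(rows),
        "auc_roc": float(roc_auc_score(y, p)),
        "auc_pr": float(average_precision_score(y, p)),
    }


# ---------------------------------------------------------------------------
# Shapley attribution (permutation estimator, exact additivity)


def permutation_shapley(
    predict,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    n_permutations: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Interventional Shapley values by permutation sampling.

    For each sampled feature permutation and background row, features are
    switched from the background value to the explained row's value in
    permutation order, and each feature is credited with the resulting change
    in ``predict``.  The telescoping sum makes per-row attributions add up
    exactly to ``predict(x) - mean(predict(background))``.
    """
    rng = rng or np.random.default_rng(0)
    n, d = X_explain.shape
    nb = len(X_background)
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        # z: (n, nb, d) current mixed rows, start at background
        z = np.broadcast_to(X_background[None, :, :], (n, nb, d)).copy()
        prev = predict(z.reshape(-1, d)).reshape(n, nb)
        for j in order:
            z[:, :, j] = X_explain[:, None, j]
            cur = predict(z.reshape(-1, d)).reshape(n, nb)
            phi[:, j] += (cur - prev).mean(axis=1)
            prev = cur
    return phi / n_permutations


def explain_top_member(
    model: EnsembleModel,
    rows: pd.DataFrame,
    n_permutations: int = 10,
    max_rows: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Shapley attribution table for the highest-weight ensemble member.

    Returns per-feature mean absolute attribution plus the mean signed
    attribution across (up to ``max_rows``) explained rows.
    """
    top = max(model.members, key=lambda m: m.weight)
    x = top.builder.transform(rows)[:max_rows]
    predict = lambda z: top.model.predict_proba(z)[:, 1]
    rng = np.random.default_rng(seed)
    phi = permutation_shapley(predict, x, top.background, n_permutations, rng)
    return pd.DataFrame(
        {
            "feature": top.builder.feature_names_,
            "mean_abs_attribution": np.abs(phi).mean(axis=0),
            "mean_attribution": phi.mean(axis=0),
        }
    ).sort_values("mean_abs_attribution", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# convenience driver


def train_ensemble(
    rows: pd.DataFrame,
    mice: pd.DataFrame,
    learners: tuple[str, ...] = LEARNERS,
    recipes: tuple[str, ...] = RECIPES,
    seed: int = 0,
    catalog: DeficitCatalog | None = None,
    plan: SplitPlan | None = None,
    **tune_kwargs,
) -> tuple[EnsembleModel, SplitPlan, pd.DataFrame, pd.DataFrame]:
    """Split, tune, and stack in one call.

    ``rows`` is the assembled row table (see :func:`assemble_rows`); it is
    reduced to complete cases for the most demanding recipe requested.
    Training touches only rows of non-test mice, so the fitted ensemble is
    unchanged if test-mouse rows are absent from the input (pass the same
    ``plan``).  Returns (model, plan, train_rows, test_rows).
    """
    catalog = catalog or default_catalog()
    top_recipe = max(recipes)
    rows = complete_rows(rows, top_recipe, catalog)
    used_mice = mice[mice["mouse_id"].isin(rows["mouse_id"])]
    master = np.random.SeedSequence(seed)
    s_split, s_tune, s_stack = (int(s.generate_state(1)[0] % (2**31 - 1))
                                for s in master.spawn(3))
    if plan is None:
        plan = split_grouped(used_mice, seed=s_split)
    train_rows = rows[~rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
    test_rows = rows[rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
    candidates = tune_candidates(
        train_rows, plan, learners=learners, recipes=recipes,
        catalog=catalog, seed=s_tune, **tune_kwargs,
    )
    model = stack(candidates, train_rows, plan, catalog=catalog, seed=s_stack)
    return model, plan, train_rows, test_rows
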