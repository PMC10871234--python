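"""Fragility Index (FgI) deficit catalog and per-assessment scoring.

The FgI is a mouse frailty index built from 30 non-invasive ordinal health
assays.  Most items are scored on a 3-level scale (0 = absent, 0.5 = mild,
1 = severe); a few are binary (0 = absent, 1 = severe).  The per-assessment
FgI score is the mean deficit level across observed items, so it ranges from
0 (no deficits) to 1 (every observed item severe).  Dermatitis is recorded in
the clinic on a 4-level scale and collapsed to 3 levels before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DeficitCatalog",
    "FgiResult",
    "default_catalog",
    "simplify_dermatitis",
    "score_assessment",
    "score_assessments",
    "cumulative_incidence",
]

#: The 30 ordinal deficit items, in conventional reporting order.
DEFAULT_ITEM_NAMES: tuple[str, ...] = (
    "breathing_rate_depth",
    "tumors",
    "head_piloerection",
    "tail_stiffening",
    "tremor",
    "coat_condition",
    "pallor_cyanosis",
    "body_condition",
    "distended_abdomen",
    "dehydration_skin_turgor",
    "dermatitis",
    "urine",
    "thoracic_mass",
    "gait_disorders",
    "paralysis",
    "rectal_prolapse",
    "eye_discharge_eyelid_inflammation",
    "kyphosis",
    "hunched",
    "changes_to_eye_globe",
    "response_to_analgesic",
    "peri_retro_orbital_swelling",
    "activity",
    "malocclusions",
    "piloerection",
    "diarrhea",
    "response_to_external_stimuli",
    "vestibular_disturbance",
    "nasal_discharge",
    "vaginal_uterine_prolapse",
)

#: Items scored absent/severe only.  The 2-level set is not enumerated by the
#: assay sheet available to us, so it is configuration: this default marks the
#: discrete presence/absence conditions as binary.
DEFAULT_TWO_LEVEL_ITEMS: frozenset[str] = frozenset(
    {
        "paralysis",
        "rectal_prolapse",
        "malocclusions",
        "diarrhea",
        "nasal_discharge",
        "vaginal_uterine_prolapse",
    }
)

_VALID_3 = frozenset({0.0, 0.5, 1.0})
_VALID_2 = frozenset({0.0, 1.0})


@dataclass(frozen=True)
class DeficitCatalog:
    """Ordered catalog of the 30 ordinal deficit items.

    Parameters
    ----------
    items : tuple of (name, n_levels)
        ``n_levels`` is 2 (scores {0, 1}) or 3 (scores {0, 0.5, 1}).
    """

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.items]
        if len(names) != 30:
            raise ValueError(f"catalog must have exactly 30 items, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("catalog item names must be unique")
        for name, lv in self.items:
            if lv not in (2, 3):
                raise ValueError(f"item {name!r}: n_levels must be 2 or 3, got {lv}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def n_levels(self, name: str) -> int:
        for n, lv in self.items:
            if n == name:
                return lv
        raise KeyError(name)

    def valid_scores(self, name: str) -> frozenset[float]:
        return _VALID_2 if self.n_levels(name) == 2 else _VALID_3

    def max_score(self, name: str) -> float:
        return 1.0


def default_catalog(two_level_items: frozenset[str] | set[str] = DEFAULT_TWO_LEVEL_ITEMS) -> DeficitCatalog:
    """The default 30-item catalog; 3-level except ``two_level_items``."""
    unknown = set(two_level_items) - set(DEFAULT_ITEM_NAMES)
    if unknown:
        raise ValueError(f"unknown two-level items: {sorted(unknown)}")
    return DeficitCatalog(
        items=tuple((n, 2 if n in two_level_items else 3) for n in DEFAULT_ITEM_NAMES)
    )


@dataclass(frozen=True)
class FgiResult:
    mouse_id: str
    date: object
    fgi_score: float  # NaN when no items observed
    n_items_observed: int
    n_severe: int


_DERMATITIS_COLLAPSE = {0: 0.0, 1: 0.5, 2: 0.5, 3: 1.0}


def simplify_dermatitis(score4: int) -> float:
    """Collapse the 4-level dermatitis grade onto the 3-level scale.

    0 -> 0 (absent), 1 and 2 -> 0.5 (mild/moderate), 3 -> 1 (severe).  Any
    monotone surjection onto {0, 0.5, 1} is defensible; this one treats the
    two intermediate grades as mild.
    """
    if score4 not in _DERMATITIS_COLLAPSE:
        raise ValueError(f"dermatitis level must be in {{0,1,2,3}}, got {score4!r}")
    return _DERMATITIS_COLLAPSE[score4]


def _validate_scores(deficits: dict[str, float], catalog: DeficitCatalog) -> None:
    for name, score in deficits.items():
        valid = catalog.valid_scores(name)  # raises KeyError on unknown item
        if score is not None and not (isinstance(score, float) and np.isnan(score)):
            if float(score) not in valid:
                raise ValueError(
                    f"item {name!r}: score {score!r} invalid for a "
                    f"{catalog.n_levels(name)}-level item"
                )


def score_assessment(
    deficits: dict[str, float],
    catalog: DeficitCatalog,
    *,
    mouse_id: str = "",
    date: object = None,
) -> FgiResult:
    """Score one assessment: mean deficit level over observed items.

    ``deficits`` maps item name to score; missing items may be absent from the
    mapping or carry NaN/None.  With zero observed items the score is NaN.
    """
    _validate_scores(deficits, catalog)
    vals = [
        float(v)
        for v in deficits.values()
        if v is not None and not (isinstance(v, float) and np.isnan(v))
    ]
    n_obs = len(vals)
    return FgiResult(
        mouse_id=mouse_id,
        date=date,
        fgi_score=float(np.mean(vals)) if n_obs else float("nan"),
        n_items_observed=n_obs,
        n_severe=int(sum(v == 1.0 for v in vals)),
    )


def score_assessments(assessments: pd.DataFrame, catalog: DeficitCatalog) -> pd.DataFrame:
    """Vectorized scoring of an assessment table.

    Returns a frame with columns mouse_id, date, fgi_score, n_items_observed,
    n_severe (one row per input row, in order).
    """
    cols = [c for c in catalog.names if c in assessments.columns]
    missing = set(catalog.names) - set(cols)
    if missing:
        raise KeyError(f"assessment table lacks catalog items: {sorted(missing)}")
    block = assessments[catalog.names].to_numpy(dtype=float)
    # validate score values per item scale
    for j, name in enumerate(catalog.names):
        col = block[:, j]
        obs = col[~np.isnan(col)]
        valid = np.array(sorted(catalog.valid_scores(name)))
        if obs.size and not np.isin(obs, valid).all():
            bad = obs[~np.isin(obs, valid)][0]
            raise ValueError(f"item {name!r}: score {bad!r} out of range")
    observed = ~np.isnan(block)
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.where(n_obs > 0, np.nansum(block, axis=1) / np.maximum(n_obs, 1), np.nan)
    n_severe = np.nansum(block == 1.0, axis=1).astype(int)
    return pd.DataFrame(
        {
            "mouse_id": assessments["mouse_id"].to_numpy(),
            "date": assessments["date"].to_numpy(),
            "fgi_score": score,
            "n_items_observed": n_obs.astype(int),
            "n_severe": n_severe,
        }
    )


def cumulative_incidence(
    assessments: pd.DataFrame,
    catalog: DeficitCatalog,
    mice: pd.DataFrame,
    group_by: str | list[str] = "strain",
) -> pd.DataFrame:
    """Per item and group: fraction of mice ever reaching the item's maximum level.

    A mouse counts toward an item's cumulative incidence when its maximum
    observed score for that item equals the item's maximum possible level.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    merged = assessments.merge(mice[["mouse_id"] + group_by], on="mouse_id", how="left")
    per_mouse_max = merged.groupby(["mouse_id"] + group_by, observed=True)[
        catalog.names
    ].max()
    rows = []
    for group_key, sub in per_mouse_max.groupby(group_by, observed=True):
        if len(sub) == 0:
            raise ValueError("empty group in cumulative_incidence")
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        for name in catalog.names:
            reached = (sub[name] == catalog.max_score(name)).sum()
            rows.append(
                dict(zip(group_by, group_key))
                | {"item": name, "proportion": reached / len(sub), "n_mice": len(sub)}
            )
    return pd.DataFrame(rows)
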