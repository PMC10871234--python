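"""Synthetic longitudinal fragility cohort generator.

Emulates the data structure of a two-cohort mouse aging study: an inbred
C57BL/6J (B6) arm of both sexes enrolled around 24 months, and a Diversity
Outbred (DO) female arm enrolled around 30 months across five diet groups
(AL, IF1, IF2, CR20, CR40).  Mice are assessed weekly from enrollment until
natural death; each visit records body weight (g), rectal temperature (C),
and the 30-item ordinal deficit vector of the Fragility Index.

Model components
----------------
* Lifespans follow a Gompertz hazard ``h(t) = a * exp(b t)`` with a per-diet
  proportional-hazards multiplier, left-truncated at the enrollment age
  (cohorts are conditioned on survival to enrollment).  Sampling uses the
  exact inverse conditional CDF.
* Terminal decline is a smooth logistic ramp in proportion of life lived
  (PLL): ``ramp(p) = 1 / (1 + exp(-k (p - p0)))`` with onset ``p0``
  (default 0.95) and steepness ``k``.  Weight and temperature drop by a
  configured magnitude times the ramp; deficit odds rise with it.
* Each deficit item follows an ordered-logit observation model in PLL with
  per-item thresholds, combined with an accumulation ("ratchet") process:
  scores never decrease unless a remission event occurs (severe deficits are
  absorbing), so deficit accumulation mirrors real frailty trajectories.
* Item-level heterogeneity: some items are near-universal late in life,
  a configurable pair is never observed (all zeros), and two items can be
  given a study "start date" to emulate assays added after study start.
* Missingness: whole visits are skipped completely at random with
  ``missing_row_prob``; individual items are masked with ``missing_item_prob``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from .fgi import DEFAULT_ITEM_NAMES, DeficitCatalog, default_catalog

__all__ = [
    "ItemParams",
    "CohortConfig",
    "GroundTruth",
    "default_item_params",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Calendar date of study day 0 (arbitrary; only differences matter).
STUDY_EPOCH = Date(2019, 9, 1)

DIETS = ("AL", "IF1", "IF2", "CR20", "CR40")


@dataclass(frozen=True)
class ItemParams:
    """Ordered-logit parameters for one deficit item.

    The linear predictor is ``slope_pll * pll + ramp_coef * ramp(pll)``;
    P(score >= mild) = sigmoid(lp - cut_mild), P(score = severe) =
    sigmoid(lp - cut_severe).  For 2-level items only ``cut_severe`` is used.
    A very large cut (e.g. 40) makes an item effectively never observed.

    Because scores accumulate over weekly visits (the ratchet), these
    per-visit probabilities act as discrete-time hazards; cuts are therefore
    placed several logits above the PLL term so that cumulative incidence,
    not the per-visit probability, lands in a realistic range.
    """

    cut_mild: float
    cut_severe: float
    slope_pll: float = 4.0
    ramp_coef: float = 3.5

    def __post_init__(self) -> None:
        if self.cut_severe < self.cut_mild:
            raise ValueError("cut_severe must be >= cut_mild")


#: Items that are near-universal in very old mice (age-graded background).
_HIGH_INCIDENCE = ("piloerection", "kyphosis", "coat_condition")
#: Items never observed by default (exercises the zero-variance filter).
_NEVER_OBSERVED = ("nasal_discharge", "vaginal_uterine_prolapse")
#: Items whose odds spike with the terminal ramp — the informative subset;
#: real frailty indices show this heterogeneity (a minority of items track
#: imminent death, the rest accumulate gradually with age).
_TERMINAL_ITEMS = (
    "breathing_rate_depth",
    "tumors",
    "body_condition",
    "tremor",
    "pallor_cyanosis",
    "dehydration_skin_turgor",
    "tail_stiffening",
    "head_piloerection",
)


def default_item_params(catalog: DeficitCatalog | None = None) -> dict[str, ItemParams]:
    """Deterministic per-item defaults with realistic heterogeneity.

    Three tiers: ~8 terminal-responsive items (non-zero ramp coefficient),
    a background of gradually accumulating items (ramp coefficient 0), and
    two never-observed items.  Thresholds are spread so that FgI scores land
    in roughly [0.02, 0.57] and most mice accumulate 4+ severe deficits
    before death.
    """
    catalog = catalog or default_catalog()
    params: dict[str, ItemParams] = {}
    rare_rank = 0
    for name in catalog.names:
        if name in _NEVER_OBSERVED:
            params[name] = ItemParams(cut_mild=40.0, cut_severe=40.0, ramp_coef=0.0)
        elif name in _TERMINAL_ITEMS:
            params[name] = ItemParams(cut_mild=6.0, cut_severe=8.4, ramp_coef=4.5)
        elif name in _HIGH_INCIDENCE:
            params[name] = ItemParams(cut_mild=5.0, cut_severe=9.5, ramp_coef=0.0)
        else:
            # deterministic spread of onset thresholds across the catalog
            cut = 6.8 + 2.2 * (rare_rank % 7) / 6.0
            params[name] = ItemParams(cut_mild=cut, cut_severe=cut + 3.2, ramp_coef=0.0)
            rare_rank += 1
    return params


def _default_enrollment() -> dict[str, float]:
    return {"B6": 730.0, "DO": 913.0}


def _default_gompertz_a() -> dict[str, float]:
    return {"B6": 3.2e-5, "DO": 9.6e-5}


def _default_gompertz_b() -> dict[str, float]:
    return {"B6": 0.006, "DO": 0.004}


def _default_diet_loghr() -> dict[str, float]:
    return {"AL": 0.0, "IF1": -0.35, "IF2": -0.6, "CR20": -0.9, "CR40": -1.3}


def _default_weight_mean() -> dict[str, float]:
    return {"B6": 33.0, "DO": 30.0}


@dataclass
class CohortConfig:
    """All data-generating assumptions for one synthetic cohort.

    Groups are (B6 x sex, diet AL) and (DO female x diet); each gets
    ``n_mice_per_group`` mice.
    """

    n_mice_per_group: int = 40
    strains: tuple[str, ...] = ("B6", "DO")
    diets: tuple[str, ...] = DIETS
    sexes: tuple[str, ...] = ("F", "M")  # used by the B6 arm; DO mice are female
    enrollment_age_days: dict[str, float] = field(default_factory=_default_enrollment)
    gompertz_a: dict[str, float] = field(default_factory=_default_gompertz_a)
    gompertz_b: dict[str, float] = field(default_factory=_default_gompertz_b)
    diet_logHR: dict[str, float] = field(default_factory=_default_diet_loghr)
    #: population decline onset (PLL); a dict maps diet -> onset for
    #: diet-specific late-life decline experiments
    decline_onset_pll: float | dict[str, float] = 0.95
    #: per-mouse SD of the decline onset (PLL units); individual mice begin
    #: terminal decline earlier or later than the population inflection
    decline_onset_sd: float = 0.012
    decline_steepness: float = 120.0
    weight_baseline_mean_g: dict[str, float] = field(default_factory=_default_weight_mean)
    weight_baseline_sd_g: float = 3.0
    weight_age_slope_g_per_day: float = -0.004
    weight_noise_sd_g: float = 1.0
    temp_baseline_C: float = 36.8
    temp_noise_sd_C: float = 0.4
    terminal_weight_drop_frac: float = 0.2
    terminal_temp_drop_C: float = 2.5
    #: lognormal coefficient of variation of per-mouse terminal drop
    #: magnitudes (sudden deaths show little decline, gradual ones a lot)
    terminal_drop_cv: float = 0.5
    item_params: dict[str, ItemParams] = field(default_factory=default_item_params)
    #: clock driving deficit accumulation: "pll" (relative to lifespan) or
    #: "age" (chronological; age is normalized by ``deficit_age_ref_days``).
    #: The terminal ramp is always on the PLL clock.
    deficit_clock: str = "pll"
    deficit_age_ref_days: float = 1100.0
    reversal_prob: float = 0.15
    missing_row_prob: float = 0.02
    missing_item_prob: float = 0.002
    #: study-day offset before which an item is not collected (late-added assays)
    item_start_day: dict[str, int] = field(
        default_factory=lambda: {"head_piloerection": 14, "thoracic_mass": 14}
    )
    assessment_interval_days: int = 7
    #: unrecorded weekly deficit updates before enrollment, so mice carry
    #: accumulated deficits at their first recorded visit
    burn_in_days: float = 365.0
    max_lifespan_days: float = 1825.0  # hard cap, ~5 years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group <= 0:
            raise ValueError("n_mice_per_group must be positive")
        onsets = (
            self.decline_onset_pll.values()
            if isinstance(self.decline_onset_pll, dict)
            else [self.decline_onset_pll]
        )
        if not all(0.0 < v <= 1.0 for v in onsets):
            raise ValueError("decline_onset_pll must be in (0, 1]")
        if self.deficit_clock not in ("pll", "age"):
            raise ValueError("deficit_clock must be 'pll' or 'age'")
        for p in (self.reversal_prob, self.missing_row_prob, self.missing_item_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for s, v in self.enrollment_age_days.items():
            if v <= 0:
                raise ValueError(f"enrollment age for {s} must be positive")
        missing = set(DEFAULT_ITEM_NAMES) - set(self.item_params)
        extra = set(self.item_params) - set(DEFAULT_ITEM_NAMES)
        if missing or extra:
            raise ValueError(
                f"item_params must cover exactly the 30 catalog items "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def groups(self) -> list[tuple[str, str, str]]:
        """(strain, sex, diet) for every cohort group."""
        out: list[tuple[str, str, str]] = []
        if "B6" in self.strains:
            out += [("B6", sex, "AL") for sex in self.sexes]
        if "DO" in self.strains:
            out += [("DO", "F", diet) for diet in self.diets]
        return out


@dataclass
class GroundTruth:
    """Generator-side truth for testing downstream estimators."""

    onset_age_days: pd.Series  # per mouse_id: decline onset age
    labels: pd.DataFrame  # per assessment row: mouse_id, date, pll, is_95pll


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _sample_truncated_gompertz(
    rng: np.random.Generator, a: float, b: float, t0: float, n: int, t_max: float
) -> np.ndarray:
    """Gompertz lifespans conditional on survival past ``t0`` (inverse CDF)."""
    u = rng.uniform(size=n)
    # S(t | t0) = exp(-(a/b) (e^{bt} - e^{bt0}));  t = (1/b) log(e^{bt0} - (b/a) log u)
    t = np.log(np.exp(b * t0) - (b / a) * np.log(u)) / b
    return np.minimum(t, t_max)


def _deficit_paths(
    rng: np.random.Generator,
    clock: np.ndarray,
    ramp: np.ndarray,
    catalog: DeficitCatalog,
    params: dict[str, ItemParams],
    reversal_prob: float,
) -> np.ndarray:
    """Simulate one mouse's (n_visits, 30) deficit scores.

    At each visit a candidate score is drawn from the ordered-logit
    cross-sectional model; the state ratchets (``max`` of state and candidate)
    except that a non-severe state may remit to the candidate with probability
    ``reversal_prob``.  Severe (1.0) is absorbing.  ``clock`` is the item
    progression variable (PLL, or normalized age under the age clock).
    """
    n = len(clock)
    names = catalog.names
    m = len(names)
    cut_mild = np.array([params[nm].cut_mild for nm in names])
    cut_severe = np.array([params[nm].cut_severe for nm in names])
    slope = np.array([params[nm].slope_pll for nm in names])
    ramp_c = np.array([params[nm].ramp_coef for nm in names])
    two_level = np.array([catalog.n_levels(nm) == 2 for nm in names])

    lp = clock[:, None] * slope[None, :] + ramp[:, None] * ramp_c[None, :]
    p_ge_mild = _sigmoid(lp - cut_mild[None, :])
    p_severe = _sigmoid(lp - cut_severe[None, :])
    u = rng.uniform(size=(n, m))
    cand = np.where(u < p_severe, 1.0, np.where(u < p_ge_mild, 0.5, 0.0))
    cand[:, two_level] = np.where(u[:, two_level] < p_severe[:, two_level], 1.0, 0.0)

    remit = rng.uniform(size=(n, m)) < reversal_prob
    scores = np.empty((n, m))
    state = cand[0]
    scores[0] = state
    for t in range(1, n):
        c = cand[t]
        up = np.maximum(state, c)
        # remission allowed only from non-severe states
        state = np.where((c < state) & remit[t] & (state < 1.0), c, up)
        scores[t] = state
    return scores


def generate_cohort(
    config: CohortConfig, catalog: DeficitCatalog | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (mice, assessments, ground_truth) tables.

    Returns
    -------
    mice : DataFrame [mouse_id, strain, sex, diet, enrollment_age_days, lifespan_days]
    assessments : DataFrame [mouse_id, date, age_days, weight_g, temp_C, <30 items>]
    ground_truth : GroundTruth
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    interval = config.assessment_interval_days

    mouse_rows: list[dict] = []
    assess_rows: list[pd.DataFrame] = []
    onset_ages: dict[str, float] = {}
    truth_rows: list[pd.DataFrame] = []

    idx = 0
    for strain, sex, diet in config.groups():
        t0 = config.enrollment_age_days[strain]
        a = config.gompertz_a[strain] * np.exp(config.diet_logHR.get(diet, 0.0))
        b = config.gompertz_b[strain]
        n = config.n_mice_per_group
        lifespans = _sample_truncated_gompertz(rng, a, b, t0, n, config.max_lifespan_days)
        # ensure at least one scheduled visit strictly before death
        lifespans = np.maximum(lifespans, t0 + 1.0)
        for k in range(n):
            mouse_id = f"{strain}-{sex}-{diet}-{idx:04d}"
            idx += 1
            lifespan = float(np.ceil(lifespans[k]))
            mouse_rows.append(
                {
                    "mouse_id": mouse_id,
                    "strain": strain,
                    "sex": sex,
                    "diet": diet,
                    "enrollment_age_days": t0,
                    "lifespan_days": lifespan,
                }
            )

            n_burn = int(config.burn_in_days // interval)
            ages_full = np.arange(
                t0 - n_burn * interval, lifespan + 0.5, interval, dtype=float
            )
            recorded = ages_full >= t0
            ages = ages_full[recorded]
            nv = len(ages)
            pll_full = ages_full / lifespan
            onset_i = (
                config.decline_onset_pll[diet]
                if isinstance(config.decline_onset_pll, dict)
                else config.decline_onset_pll
            )
            if config.decline_onset_sd > 0:
                onset_i = float(
                    np.clip(
                        rng.normal(onset_i, config.decline_onset_sd), 0.05, 1.0
                    )
                )
            ramp_full = _sigmoid(config.decline_steepness * (pll_full - onset_i))
            pll, ramp = pll_full[recorded], ramp_full[recorded]
            onset_ages[mouse_id] = onset_i * lifespan

            base_w = rng.normal(config.weight_baseline_mean_g[strain], config.weight_baseline_sd_g)
            cv = config.terminal_drop_cv
            if cv > 0:
                sig = np.sqrt(np.log(1.0 + cv * cv))
                drop_mult = rng.lognormal(-0.5 * sig * sig, sig, size=2)
            else:
                drop_mult = np.ones(2)
            weight = (
                base_w
                + config.weight_age_slope_g_per_day * (ages - t0)
                - config.terminal_weight_drop_frac * drop_mult[0] * base_w * ramp
                + rng.normal(0.0, config.weight_noise_sd_g, nv)
            )
            temp = (
                config.temp_baseline_C
                - config.terminal_temp_drop_C * drop_mult[1] * ramp
                + rng.normal(0.0, config.temp_noise_sd_C, nv)
            )
            clock_full = (
                pll_full
                if config.deficit_clock == "pll"
                else ages_full / config.deficit_age_ref_days
            )
            scores = _deficit_paths(
                rng, clock_full, ramp_full, catalog, config.item_params, config.reversal_prob
            )[recorded]

            study_day = (ages - t0).astype(int)
            # late-added items: masked before their start day
            for nm, start in config.item_start_day.items():
                j = catalog.names.index(nm)
                scores[study_day < start, j] = np.nan
            if config.missing_item_prob > 0:
                mask = rng.uniform(size=scores.shape) < config.missing_item_prob
                scores[mask] = np.nan
            keep = np.ones(nv, dtype=bool)
            if config.missing_row_prob > 0:
                keep = rng.uniform(size=nv) >= config.missing_row_prob
                keep[0] = True  # enrollment visit always recorded

            frame = pd.DataFrame(scores, columns=catalog.names)
            frame.insert(0, "temp_C", np.round(temp, 2))
            frame.insert(0, "weight_g", np.round(weight, 2))
            frame.insert(0, "age_days", ages)
            frame.insert(
                0,
                "date",
                [STUDY_EPOCH + timedelta(days=int(d)) for d in study_day],
            )
            frame.insert(0, "mouse_id", mouse_id)
            truth = pd.DataFrame(
                {
                    "mouse_id": mouse_id,
                    "date": frame["date"],
                    "pll": pll,
                    "is_95pll": pll > 0.95,
                }
            )
            assess_rows.append(frame.loc[keep])
            truth_rows.append(truth.loc[keep])

    mice = pd.DataFrame(mouse_rows)
    assessments = pd.concat(assess_rows, ignore_index=True)
    ground_truth = GroundTruth(
        onset_age_days=pd.Series(onset_ages, name="onset_age_days"),
        labels=pd.concat(truth_rows, ignore_index=True),
    )
    return mice, assessments, ground_truth


# ---------------------------------------------------------------------------
# on-disk round trip


def write_cohort(mice: pd.DataFrame, assessments: pd.DataFrame, path) -> None:
    """Write ``mice.csv`` and ``assessments.csv`` under directory ``path``."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _validate_tables(mice, assessments)
    mice.to_csv(path / "mice.csv", index=False)
    out = assessments.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path / "assessments.csv", index=False)


def read_cohort(path, catalog: DeficitCatalog | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; validates invariants."""
    from pathlib import Path

    catalog = catalog or default_catalog()
    path = Path(path)
    mice = pd.read_csv(path / "mice.csv")
    assessments = pd.read_csv(path / "assessments.csv")
    expected_mice = ["mouse_id", "strain", "sex", "diet", "enrollment_age_days", "lifespan_days"]
    if list(mice.columns) != expected_mice:
        raise ValueError(f"malformed mice.csv header: {list(mice.columns)}")
    expected_assess = ["mouse_id", "date", "age_days", "weight_g", "temp_C"] + catalog.names
    if list(assessments.columns) != expected_assess:
        raise ValueError(f"malformed assessments.csv header: {list(assessments.columns)}")
    assessments["date"] = pd.to_datetime(assessments["date"]).dt.date
    _validate_tables(mice, assessments, catalog)
    return mice, assessments


def _validate_tables(
    mice: pd.DataFrame, assessments: pd.DataFrame, catalog: DeficitCatalog | None = None
) -> None:
    catalog = catalog or default_catalog()
    if (mice["lifespan_days"] <= mice["enrollment_age_days"]).any():
        bad = mice.loc[mice["lifespan_days"] <= mice["enrollment_age_days"], "mouse_id"].iloc[0]
        raise ValueError(f"mouse {bad!r}: lifespan must exceed enrollment age")
    dup = assessments.duplicated(subset=["mouse_id", "date"])
    if dup.any():
        row = assessments.loc[dup].index[0]
        raise ValueError(f"duplicate (mouse_id, date) at assessments row {row}")
    for name in catalog.names:
        if name not in assessments.columns:
            continue
        col = assessments[name].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        valid = np.array(sorted(catalog.valid_scores(name)))
        if obs.size and not np.isin(obs, valid).all():
            bad_val = obs[~np.isin(obs, valid)][0]
            bad_row = int(np.flatnonzero(~np.isin(col, valid) & ~np.isnan(col))[0])
            raise ValueError(
                f"item {name!r}: invalid score {bad_val} at assessments row {bad_row}"
            )
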