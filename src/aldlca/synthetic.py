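"""Synthetic aging-panel generator with known latent-class structure.

Emulates a four-wave panel of adults aged 50+ in the style of the
Mexican Health and Aging Study: ~12 four-year birth cohorts, waves at
2001/2003/2012/2015, a refreshment sample entering at the third wave,
age-increasing attrition, and nine binary household-composition markers
(children present, adult children, studying/working adult children,
children's partners, own partner/spouse, nonrelatives, other relatives,
grandchildren) plus respondent sex as a tenth item.

Each person carries a fixed latent class; given class and design age the
markers are independent Bernoulli draws from logistic-in-age prevalence
curves (partner presence declining with age, grandchildren rising, ...).
That conditional-independence structure is exactly what the downstream
latent class model assumes, so the generator provides clean ground truth
for parameter-recovery and class-enumeration tests.

Marker probabilities are evaluated at the *nominal mean age of the
design time point* a record maps to, so every cell of the person x
time-point x item array is exactly homogeneous within class; records
that fall off the design grid (aged past the last column) use the
person's actual age, clamped to the curve domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import MARKER_COLUMNS, PANEL_COLUMNS, DesignSchedule, map_records, mhas_schedule

AGE_LO, AGE_HI = 45.0, 100.0
_MAX_ABS_LOGIT = 30.0


class ConfigurationError(ValueError):
    """A synthetic configuration implies degenerate probabilities."""


def curve_through(age1: float, p1: float, age2: float, p2: float) -> tuple[float, float]:
    """(intercept, slope) of the logistic curve through (age1, p1), (age2, p2)."""
    b = (logit(p2) - logit(p1)) / (age2 - age1)
    a = logit(p1) - b * age1
    return float(a), float(b)


# Population-level (age 52, age 86) prevalence endpoints for the nine
# household markers, matching the descriptive drift of an MHAS-like panel:
# children in household and own partner decline with age, children's
# partners / other relatives / grandchildren rise.
_MARKER_ENDPOINTS = [
    (0.822, 0.551),   # 1 children living in the household
    (0.695, 0.548),   # 2 children >= 18
    (0.129, 0.003),   # 3 studying children >= 18
    (0.482, 0.379),   # 4 working children >= 18
    (0.116, 0.172),   # 5 children's partners
    (0.778, 0.352),   # 6 index adult's partner or spouse
    (0.008, 0.024),   # 7 nonrelatives
    (0.316, 0.408),   # 8 other relatives
    (0.208, 0.343),   # 9 grandchildren / great-grandchildren
]

# Additive logit offsets per class giving three well-separated household
# regimes: class 0 large multigenerational households; class 1 couple-based
# emptying-nest households; class 2 small, mostly unpartnered households.
_CLASS_OFFSETS = np.array(
    [
        #   c0      c1      c2
        [+3.00, +1.20, -3.30],   # children in household
        [+3.00, -0.75, -2.70],   # children >= 18
        [+1.80, +0.45, -2.25],   # studying children
        [+2.70, -0.30, -2.40],   # working children
        [+3.30, -2.70, -2.70],   # children's partners
        [+0.75, +3.30, -3.75],   # partner/spouse
        [+0.90, -1.20, +1.20],   # nonrelatives
        [+2.25, -2.70, +1.50],   # other relatives
        [+3.75, -3.00, -0.75],   # grandchildren
    ]
)


def default_item_curves(s_true: int = 3) -> np.ndarray:
    """(s_true, 9, 2) array of per-class (intercept, slope) marker curves.

    The population curve of each marker is anchored at the endpoint
    prevalences above; classes shift its intercept by a fixed offset.
    """
    if s_true > _CLASS_OFFSETS.shape[1]:
        raise ConfigurationError("default curves define at most 3 classes")
    curves = np.zeros((s_true, 9, 2))
    for i, (p1, p9) in enumerate(_MARKER_ENDPOINTS):
        a, b = curve_through(52.0, p1, 86.0, p9)
        for s in range(s_true):
            curves[s, i] = (a + _CLASS_OFFSETS[i, s], b)
    return curves


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Defaults are the package's desk-scale emulation of the four-wave
    MHAS panel: 8,000 baseline entrants (2001), a 2,000-person
    refreshment sample (2012), three latent household classes, and an
    age-increasing per-transition attrition hazard calibrated so the
    mean consecutive-wave overlap is near the reported ~57%.
    """

    n_baseline: int = 8_000
    n_refresh: int = 2_000
    s_true: int = 3
    class_proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    #: (s_true, 9, 2) per class x marker: logistic intercept and slope in age.
    item_curves: np.ndarray = field(default_factory=default_item_curves)
    #: per-class probability that the respondent is a woman (item 10).
    sex_probs: tuple[float, ...] = (0.55, 0.35, 0.75)
    birth_year_range: tuple[int, int] = (1909, 1951)
    refresh_birth_year_range: tuple[int, int] = (1951, 1962)
    wave_years: tuple[int, ...] = (2001, 2003, 2012, 2015)
    #: per-transition dropout hazard: base + per_year * (age - 50), clipped.
    attrition_hazard: tuple[float, float] = (0.22, 0.004)
    #: optional per-class hazard multipliers (class-dependent attrition switch).
    class_attrition_multipliers: tuple[float, ...] | None = None
    #: draw sex once per person and replicate it (induces within-class serial
    #: correlation the latent class model does not describe); default draws it
    #: independently per time point given class, like every other item.
    sex_time_constant: bool = False
    seed: int = 2001

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_curves", np.asarray(self.item_curves, float))
        self.validate()

    def validate(self) -> None:
        if self.n_baseline < 1:
            raise ConfigurationError("n_baseline must be >= 1")
        if self.n_refresh < 0:
            raise ConfigurationError("n_refresh must be >= 0")
        props = np.asarray(self.class_proportions, float)
        if len(props) != self.s_true or len(props) == 0:
            raise ConfigurationError("class_proportions must have length s_true")
        if abs(props.sum() - 1.0) > 1e-12 or (props <= 0).any():
            raise ConfigurationError("class_proportions must be a positive simplex")
        if list(self.wave_years) != sorted(set(self.wave_years)):
            raise ConfigurationError("wave_years must be strictly increasing")
        if self.item_curves.shape != (self.s_true, 9, 2):
            raise ConfigurationError("item_curves must be (s_true, 9, 2)")
        if len(self.sex_probs) != self.s_true or not all(
            0 < p < 1 for p in self.sex_probs
        ):
            raise ConfigurationError("sex_probs must be s_true values in (0,1)")
        a = self.item_curves[..., 0]
        b = self.item_curves[..., 1]
        for age in (AGE_LO, AGE_HI):
            if (np.abs(a + b * age) > _MAX_ABS_LOGIT).any():
                raise ConfigurationError(
                    "item curves leave (0,1) beyond tolerance on [45, 100]"
                )
        base, slope = self.attrition_hazard
        if not (0 <= base < 1):
            raise ConfigurationError("attrition base hazard must be in [0,1)")
        if self.class_attrition_multipliers is not None and len(
            self.class_attrition_multipliers
        ) != self.s_true:
            raise ConfigurationError("need one attrition multiplier per class")


@dataclass
class TruePopulation:
    """A generated panel together with its generating truth."""

    panel: pd.DataFrame
    #: per-person latent class label (0-based), indexed by person_id.
    true_class: pd.Series
    #: (s_true, 10, 9) generating item probabilities at the design time points.
    true_params: np.ndarray
    config: SyntheticConfig


def evaluate_item_curves(
    config: SyntheticConfig, ages: np.ndarray | list[float]
) -> np.ndarray:
    """Class x item x age probability array (10 items: 9 markers + sex).

    Sex is time-constant, so its row repeats ``sex_probs`` at every age.
    """
    ages = np.asarray(ages, dtype=float)
    if (ages < AGE_LO).any() or (ages > AGE_HI).any():
        raise ValueError(f"ages must lie within [{AGE_LO:g}, {AGE_HI:g}]")
    a = config.item_curves[..., 0][:, :, None]          # (S, 9, 1)
    b = config.item_curves[..., 1][:, :, None]
    probs = expit(a + b * ages[None, None, :])          # (S, 9, A)
    if (probs <= 0).any() or (probs >= 1).any():
        raise ConfigurationError("curve probabilities left (0,1)")
    sex = np.broadcast_to(
        np.asarray(config.sex_probs, float)[:, None, None],
        (config.s_true, 1, len(ages)),
    )
    return np.concatenate([probs, sex], axis=1)         # (S, 10, A)


def _hazard(config: SyntheticConfig, age: np.ndarray, cls: np.ndarray) -> np.ndarray:
    base, slope = config.attrition_hazard
    h = base + slope * np.maximum(age - 50.0, 0.0)
    if config.class_attrition_multipliers is not None:
        h = h * np.asarray(config.class_attrition_multipliers, float)[cls]
    return np.clip(h, 0.0, 0.95)


def generate_population(
    config: SyntheticConfig, schedule: DesignSchedule | None = None
) -> TruePopulation:
    """Draw a complete synthetic panel under the configured conditions.

    Birth years are uniform over the (entry-wave-truncated) ranges; the
    latent class is a single multinomial draw per person; markers are
    independent Bernoulli given (class, design age); attrition is a
    monotone per-transition dropout (once gone, never returns);
    refreshment persons first appear at the third wave.  Identical
    configs (including the seed) give byte-identical panels.
    """
    schedule = schedule or mhas_schedule()
    rng = np.random.default_rng(config.seed)
    waves = np.asarray(config.wave_years)

    lo, hi = config.birth_year_range
    hi = min(hi, int(waves[0]) - 50)
    if lo > hi:
        raise ConfigurationError("empty baseline birth-year range after age-50 cut")
    births = [rng.integers(lo, hi + 1, size=config.n_baseline)]
    entry = [np.full(config.n_baseline, int(waves[0]))]
    if config.n_refresh > 0:
        if len(waves) < 3:
            raise ConfigurationError("a refreshment sample needs >= 3 waves")
        rlo, rhi = config.refresh_birth_year_range
        rhi = min(rhi, int(waves[2]) - 50)
        if rlo > rhi:
            raise ConfigurationError("empty refreshment birth-year range")
        births.append(rng.integers(rlo, rhi + 1, size=config.n_refresh))
        entry.append(np.full(config.n_refresh, int(waves[2])))
    birth_year = np.concatenate(births)
    entry_wave = np.concatenate(entry)
    n = len(birth_year)
    person_id = np.arange(1, n + 1)

    props = np.asarray(config.class_proportions, float)
    cls = rng.choice(config.s_true, size=n, p=props)
    sex = (rng.random(n) < np.asarray(config.sex_probs, float)[cls]).astype(np.uint8)

    # wave participation: present at entry, then survive each transition
    present = np.zeros((n, len(waves)), dtype=bool)
    for k, w in enumerate(waves):
        present[:, k] = entry_wave == w
    for k in range(1, len(waves)):
        at_risk = present[:, k - 1]
        age_next = waves[k] - birth_year
        drop = rng.random(n) < _hazard(config, age_next.astype(float), cls)
        present[:, k] |= at_risk & ~drop

    # long-format records for every (person, wave) present
    rows_p, rows_w = np.nonzero(present)
    rec = pd.DataFrame(
        {
            "person_id": person_id[rows_p],
            "wave_year": waves[rows_w],
            "age": waves[rows_w] - birth_year[rows_p],
            "sex": sex[rows_p],
        }
    )
    # design age: nominal mean age of the mapped time point, else actual age
    rec = map_records(rec, schedule)  # sorted by (person, wave)
    rec_cls = cls[rec["person_id"].to_numpy() - 1]
    col = rec["column"].to_numpy(dtype=float, na_value=np.nan)
    design_age = rec["age"].to_numpy(dtype=float)
    in_design = ~np.isnan(col)
    nominal = np.asarray(schedule.nominal_ages)
    design_age[in_design] = nominal[col[in_design].astype(int) - 1]
    design_age = np.clip(design_age, AGE_LO, AGE_HI)

    a = config.item_curves[..., 0]   # (S, 9)
    b = config.item_curves[..., 1]
    p = expit(a[rec_cls] + b[rec_cls] * design_age[:, None])   # (rows, 9)
    draws = (rng.random(p.shape) < p).astype(np.uint8)
    for i, name in enumerate(MARKER_COLUMNS):
        rec[name] = draws[:, i]
    if not config.sex_time_constant:
        q = np.asarray(config.sex_probs, float)[rec_cls]
        rec["sex"] = (rng.random(len(q)) < q).astype(np.uint8)

    panel = rec[PANEL_COLUMNS].reset_index(drop=True)
    true_class = pd.Series(cls, index=pd.Index(person_id, name="person_id"),
                           name="true_class")
    true_params = evaluate_item_curves(config, np.asarray(schedule.nominal_ages))
    return TruePopulation(panel=panel, true_class=true_class,
                          true_params=true_params, config=config)


def write_panel_csv(pop: TruePopulation, panel_path, truth_path=None) -> None:
    """Write the panel (and optionally the person -> true-class table) as CSV."""
    pop.panel.to_csv(panel_path, index=False)
    if truth_path is not None:
        pop.true_class.reset_index().to_csv(truth_path, index=False)
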