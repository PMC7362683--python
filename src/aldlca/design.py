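"""Accelerated longitudinal (cohort-sequential) design bookkeeping.

A short multi-wave panel of adults aged 50+ is rearranged into a single
long age axis: the 50+ population is split into nine age columns, every
respondent is anchored to a birth cohort from their age at first
interview, and each follow-up wave advances a cohort a fixed number of
columns along the axis.  Linking the overlapping cohort segments yields
an approximate 30-year observation window from four interview waves.

The module owns three pieces of bookkeeping:

* cohort assignment from birth year (:func:`assign_cohort`);
* the wave -> age-column advance schedule (:func:`column_for`);
* the rearrangement of a long panel into the person x time-point x item
  array with its planned-missingness mask (:func:`rearrange`), plus the
  wave x column and cohort x column tally tables (:func:`count_tables`).

Columns and time points are 1-based throughout (t = 1..9).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = [f"marker_{i}" for i in range(1, 10)]
#: item order in the ALD array: the nine household markers, then respondent sex
#: replicated across time points as item 10.
ITEM_NAMES = MARKER_COLUMNS + ["sex"]
PANEL_COLUMNS = ["person_id", "wave_year", "age", "sex"] + MARKER_COLUMNS


class OutOfDesignError(ValueError):
    """A birth year / age combination falls outside every cohort bin."""


class UnknownWaveError(ValueError):
    """A wave year has no column offset for the given entry wave."""


class DuplicateRecordError(ValueError):
    """A (person, wave) pair appears more than once in a panel."""


@dataclass(frozen=True)
class CohortBin:
    cohort: int
    birth_lo: int
    birth_hi: int  # inclusive
    entry_wave: int

    def contains(self, birth_year: int) -> bool:
        return self.birth_lo <= birth_year <= self.birth_hi


@dataclass(frozen=True)
class DesignSchedule:
    """Wave years, age columns, cohort bins and the column-advance rules."""

    wave_years: tuple[int, ...]
    #: (lo, hi) age brackets; hi is None for the open-ended last bracket.
    age_brackets: tuple[tuple[int, int | None], ...]
    #: nominal mean age of each column, used as the design time-point age.
    nominal_ages: tuple[float, ...]
    cohort_bins: tuple[CohortBin, ...]
    #: entry wave -> {wave -> column advance relative to the baseline column}
    wave_column_offsets: dict[int, dict[int, int]]
    #: entry wave -> cohort occupying column 1 at that wave.
    anchor_cohorts: dict[int, int]

    def __post_init__(self) -> None:
        if list(self.wave_years) != sorted(set(self.wave_years)):
            raise ValueError("wave_years must be strictly increasing")
        cohorts = [b.cohort for b in self.cohort_bins]
        if cohorts != sorted(cohorts):
            raise ValueError("cohort_bins must be ordered by cohort id")
        for entry, offs in self.wave_column_offsets.items():
            waves = sorted(offs)
            if [offs[w] for w in waves] != sorted(set(offs[w] for w in waves)):
                raise ValueError(
                    f"offsets for entry wave {entry} must increase with wave year"
                )

    @property
    def n_columns(self) -> int:
        return len(self.age_brackets)

    @property
    def n_timepoints(self) -> int:
        return self.n_columns

    @property
    def entry_waves(self) -> tuple[int, ...]:
        return tuple(sorted(self.anchor_cohorts))

    def entry_wave_for(self, first_wave: int) -> int:
        """Anchor entry wave for a person first observed at ``first_wave``."""
        candidates = [w for w in self.entry_waves if w <= first_wave]
        if not candidates:
            raise OutOfDesignError(
                f"first observed wave {first_wave} precedes all entry waves"
            )
        return max(candidates)

    def column_for_age(self, age: int) -> int:
        """1-based age column containing ``age`` (entry-age bracketing)."""
        for j, (lo, hi) in enumerate(self.age_brackets, start=1):
            if age >= lo and (hi is None or age <= hi):
                return j
        raise OutOfDesignError(f"age {age} below the design range")

    def baseline_column(self, cohort: int, entry_wave: int) -> int:
        """Column a cohort occupies at its entry wave."""
        col = self.anchor_cohorts[entry_wave] - cohort + 1
        if not 1 <= col <= self.n_columns:
            raise OutOfDesignError(
                f"cohort {cohort} has no baseline column at entry wave {entry_wave}"
            )
        return col


def mhas_schedule() -> DesignSchedule:
    """The four-wave, nine-column, twelve-cohort schedule of the MHAS design.

    Waves 2001/2003/2012/2015; age columns [50-53] ... [82+] with nominal
    mean ages 52 ... 86; cohorts 1-9 enter in 2001 (anchor: cohort 9 in
    column 1) and the refreshment cohorts 10-12 enter in 2012 (anchor:
    cohort 12 in column 1).  Note bins 9 [1948-1951] and 10 [1951-1954]
    deliberately share 1951: which applies depends on the entry wave.
    """
    bins_2001 = [
        (1, 1909, 1919), (2, 1920, 1923), (3, 1924, 1927), (4, 1928, 1931),
        (5, 1932, 1935), (6, 1936, 1939), (7, 1940, 1943), (8, 1944, 1947),
        (9, 1948, 1951),
    ]
    bins_2012 = [(10, 1951, 1954), (11, 1955, 1958), (12, 1959, 1962)]
    cohort_bins = tuple(
        [CohortBin(c, lo, hi, 2001) for c, lo, hi in bins_2001]
        + [CohortBin(c, lo, hi, 2012) for c, lo, hi in bins_2012]
    )
    return DesignSchedule(
        wave_years=(2001, 2003, 2012, 2015),
        age_brackets=((50, 53), (54, 57), (58, 61), (62, 65), (66, 69),
                      (70, 73), (74, 77), (78, 81), (82, None)),
        nominal_ages=(52.0, 55.0, 59.0, 63.0, 67.0, 71.0, 75.0, 81.0, 86.0),
        cohort_bins=cohort_bins,
        wave_column_offsets={
            2001: {2001: 0, 2003: 1, 2012: 3, 2015: 4},
            2012: {2012: 0, 2015: 1},
        },
        anchor_cohorts={2001: 9, 2012: 12},
    )


#: Published wave x age-column observation counts of the MHAS 2001-2015 panel
#: (rows: interview waves; columns: age columns 1..9).  These printed counts
#: are the input for the cell-level cohort tabulation.
MHAS_TABLE1 = pd.DataFrame(
    [
        [2804, 2447, 2023, 1674, 1348, 1339, 688, 696, 11],
        [0, 2598, 2288, 1891, 1584, 1283, 1305, 640, 667],
        [1663, 2008, 1508, 2473, 1987, 1536, 1216, 1556, 393],
        [0, 1460, 1803, 1344, 2345, 1921, 1407, 1077, 1468],
    ],
    index=pd.Index([2001, 2003, 2012, 2015], name="wave_year"),
    columns=pd.Index(range(1, 10), name="column"),
)


@dataclass
class ALDMatrix:
    """Person x time-point x item array with its observation mask.

    ``values[n, i, t]`` is the binary response of person ``n`` on item
    ``i`` (0-based; order :data:`ITEM_NAMES`) at design time point ``t``
    (0-based), defined only where ``observed[n, i, t]`` is True.
    """

    values: np.ndarray          # (n, n_items, n_timepoints) uint8
    observed: np.ndarray        # same shape, bool
    person_id: np.ndarray       # (n,)
    cohort: np.ndarray          # (n,) int
    group: np.ndarray | None = None  # (n,) labels after group_cohorts
    #: (n, n_waves) interview participation, incl. waves mapped past the last
    #: column; filled by rearrange, None for hand-built matrices.
    wave_presence: np.ndarray | None = None
    wave_years: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must share a shape")
        if self.values.ndim != 3:
            raise ValueError("values must be person x item x time-point")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def n_cells(self) -> int:
        return self.n_items * self.n_timepoints

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, O): responses-with-zeros and observation mask, (n, items*timepoints)."""
        n = self.n_persons
        O = self.observed.reshape(n, -1).astype(np.float64)
        X = self.values.reshape(n, -1).astype(np.float64) * O
        return X, O

    def observed_timepoints(self) -> np.ndarray:
        """(n, n_timepoints) bool: any item observed at that time point."""
        return self.observed.any(axis=1)


def assign_cohort(
    birth_year: int, schedule: DesignSchedule, entry_wave: int | None = None
) -> int:
    """Cohort id whose birth-year bin contains ``birth_year``.

    Where bins overlap (a refreshment bin can share a year with the
    oldest panel bin), an ``entry_wave`` disambiguates; without one the
    lowest cohort id wins.
    """
    candidates = [b for b in schedule.cohort_bins if b.contains(int(birth_year))]
    if not candidates:
        raise OutOfDesignError(f"birth year {birth_year} outside every cohort bin")
    if entry_wave is not None:
        matching = [b for b in candidates if b.entry_wave == entry_wave]
        if matching:
            candidates = matching
    return min(candidates, key=lambda b: b.cohort).cohort


def column_for(
    entry_wave: int,
    baseline_column: int,
    wave: int,
    schedule: DesignSchedule,
) -> int | None:
    """Age column occupied at ``wave`` by a person whose entry-wave column
    was ``baseline_column``; None once the person has aged out of column 9."""
    if wave < entry_wave:
        raise ValueError(f"wave {wave} precedes entry wave {entry_wave}")
    if not 1 <= baseline_column <= schedule.n_columns:
        raise ValueError(f"baseline column {baseline_column} out of range")
    offsets = schedule.wave_column_offsets[entry_wave]
    if wave not in offsets:
        raise UnknownWaveError(f"no offset for wave {wave} (entry {entry_wave})")
    col = baseline_column + offsets[wave]
    return col if col <= schedule.n_columns else None


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("person_id", "wave_year", "age") if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks required columns: {missing}")
    dup = panel.duplicated(["person_id", "wave_year"])
    if dup.any():
        bad = panel.loc[dup, "person_id"].unique()[:5]
        raise DuplicateRecordError(
            f"duplicate (person, wave) records, e.g. persons {list(bad)}"
        )
    return panel.sort_values(["person_id", "wave_year"], kind="mergesort")


def map_records(panel: pd.DataFrame, schedule: DesignSchedule) -> pd.DataFrame:
    """Per-record design coordinates for a long panel.

    Returns the panel (sorted by person, wave) with added columns
    ``entry_wave``, ``birth_year``, ``cohort``, ``baseline_column`` and
    ``column`` (pandas nullable Int64; <NA> where the record falls past
    the last age column).  Persons outside every cohort bin are dropped
    with a logged count.
    """
    df = _validate_panel(panel).reset_index(drop=True).copy()

    birth = pd.Series(df["wave_year"].to_numpy() - df["age"].to_numpy())
    by_person = birth.groupby(df["person_id"], sort=False)
    b_span = by_person.transform("max") - by_person.transform("min")
    if (b_span > 1).any():
        bad = df.loc[b_span > 1, "person_id"].unique()[:5]
        raise ValueError(
            f"inconsistent ages within person (birth year varies > 1), e.g. {list(bad)}"
        )
    birth_year = by_person.transform("first").astype(int)

    grp = df.groupby("person_id", sort=False)
    first_wave = grp["wave_year"].transform("min")
    entry = first_wave.map(schedule.entry_wave_for)

    first_rec = df["wave_year"].eq(first_wave)
    if (df.loc[first_rec, "age"] < 50).any():
        bad = df.loc[first_rec & (df["age"] < 50), "person_id"].unique()[:5]
        raise OutOfDesignError(f"age < 50 at entry, e.g. persons {list(bad)}")

    cohort = np.full(len(df), np.nan)
    ent = entry.to_numpy()
    byr = birth_year.to_numpy()
    for e in np.unique(ent):
        sel_idx = np.flatnonzero(ent == e)
        years = byr[sel_idx]
        for y in np.unique(years):
            try:
                c = assign_cohort(int(y), schedule, entry_wave=int(e))
            except OutOfDesignError:
                continue
            cohort[sel_idx[years == y]] = c
    out_of_design = np.isnan(cohort)
    if out_of_design.any():
        n_drop = df.loc[out_of_design, "person_id"].nunique()
        logger.warning("dropping %d persons outside every cohort bin", n_drop)
        keep = ~out_of_design
        df = df[keep].reset_index(drop=True)
        cohort = cohort[keep]
        ent, byr = ent[keep], byr[keep]

    df["entry_wave"] = ent
    df["birth_year"] = byr
    df["cohort"] = cohort.astype(int)
    df["baseline_column"] = [
        schedule.baseline_column(int(c), int(e))
        for c, e in zip(df["cohort"], df["entry_wave"])
    ]

    cols: list[int | None] = []
    for e, b, w in zip(df["entry_wave"], df["baseline_column"], df["wave_year"]):
        cols.append(column_for(int(e), int(b), int(w), schedule))
    df["column"] = pd.array(cols, dtype="Int64")
    return df


def rearrange(panel: pd.DataFrame, schedule: DesignSchedule) -> ALDMatrix:
    """Rearrange a long panel into the person x time-point x item array.

    Each wave record lands in the age column given by the person's
    baseline column plus the wave's column advance; records past the last
    column contribute no slot.  The cohort comes from the birth year at
    first interview.
    """
    mapped = map_records(panel, schedule)
    items = [c for c in ITEM_NAMES if c in mapped.columns]
    if not items:
        raise ValueError("panel has no marker/sex item columns")

    persons = mapped["person_id"].drop_duplicates()
    index = pd.Series(np.arange(len(persons)), index=persons)
    n, n_items, n_t = len(persons), len(ITEM_NAMES), schedule.n_timepoints

    values = np.zeros((n, n_items, n_t), dtype=np.uint8)
    observed = np.zeros((n, n_items, n_t), dtype=bool)

    in_design = mapped["column"].notna()
    rows = index[mapped.loc[in_design, "person_id"]].to_numpy()
    tcols = mapped.loc[in_design, "column"].to_numpy(dtype=int) - 1
    for i, item in enumerate(ITEM_NAMES):
        if item not in mapped.columns:
            continue
        vals = mapped.loc[in_design, item].to_numpy()
        ok = ~pd.isna(vals)
        values[rows[ok], i, tcols[ok]] = vals[ok].astype(np.uint8)
        observed[rows[ok], i, tcols[ok]] = True

    cohort = (
        mapped.drop_duplicates("person_id").set_index("person_id")["cohort"].loc[
            persons
        ]
    )
    wave_pos = {w: k for k, w in enumerate(schedule.wave_years)}
    presence = np.zeros((n, len(schedule.wave_years)), dtype=bool)
    known = mapped["wave_year"].isin(wave_pos)
    presence[
        index[mapped.loc[known, "person_id"]].to_numpy(),
        mapped.loc[known, "wave_year"].map(wave_pos).to_numpy(),
    ] = True
    return ALDMatrix(
        values=values,
        observed=observed,
        person_id=persons.to_numpy(),
        cohort=cohort.to_numpy(dtype=int),
        wave_presence=presence,
        wave_years=tuple(schedule.wave_years),
    )


def _cohort_for_cell(wave: int, col: int, schedule: DesignSchedule) -> int:
    """Cohort occupying a (wave, column) cell of the wave x column table."""
    entry = schedule.entry_wave_for(wave)
    basecol = col - schedule.wave_column_offsets[entry][wave]
    cohort = schedule.anchor_cohorts[entry] - (basecol - 1)
    bins = {b.cohort for b in schedule.cohort_bins}
    if basecol < 1 or cohort not in bins:
        raise OutOfDesignError(f"cell (wave {wave}, column {col}) maps to no cohort")
    return cohort


def count_tables(
    panel: pd.DataFrame | None,
    schedule: DesignSchedule,
    *,
    cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wave x column and cohort x column observation-count tables.

    Record mode (``panel`` given): tallies the mapped records of a long
    panel.  Cell mode (``cells`` given): takes a pre-tabulated
    wave x column count matrix (e.g. the published wave table) and
    redistributes every cell to its cohort via the anchor/offset rule,
    reconstructing the cohort staircase without micro-data.
    """
    if (panel is None) == (cells is None):
        raise ValueError("give exactly one of panel / cells")

    waves = list(schedule.wave_years)
    cols = list(range(1, schedule.n_columns + 1))
    cohorts = sorted({b.cohort for b in schedule.cohort_bins}, reverse=True)
    wave_tab = pd.DataFrame(0, index=pd.Index(waves, name="wave_year"),
                            columns=pd.Index(cols, name="column"))
    cohort_tab = pd.DataFrame(0, index=pd.Index(cohorts, name="cohort"),
                              columns=pd.Index(cols, name="column"))

    if cells is not None:
        for w in cells.index:
            for c in cells.columns:
                count = int(cells.loc[w, c])
                if count == 0:
                    continue
                wave_tab.loc[int(w), int(c)] = count
                cohort_tab.loc[_cohort_for_cell(int(w), int(c), schedule), int(c)] += (
                    count
                )
        return wave_tab, cohort_tab

    if len(panel) == 0:
        return wave_tab, cohort_tab
    mapped = map_records(panel, schedule)
    mapped = mapped[mapped["column"].notna()]
    for (w, c), sub in mapped.groupby(["wave_year", "column"]):
        wave_tab.loc[int(w), int(c)] = len(sub)
    for (g, c), sub in mapped.groupby(["cohort", "column"]):
        cohort_tab.loc[int(g), int(c)] = len(sub)
    return wave_tab, cohort_tab


DEFAULT_GROUPING = {c: "G1" for c in range(1, 7)}
DEFAULT_GROUPING.update({c: "G2" for c in range(7, 10)})
DEFAULT_GROUPING.update({c: "G3" for c in range(10, 13)})


def group_cohorts(
    ald: ALDMatrix, grouping: dict[int, object] | None = None
) -> ALDMatrix:
    """Attach an aggregated group label per person (default: birth decades
    G1 = cohorts 1-6, G2 = 7-9, G3 = 10-12)."""
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    present = np.unique(ald.cohort)
    missing = [int(c) for c in present if int(c) not in grouping]
    if missing:
        raise KeyError(f"cohorts missing from grouping map: {missing}")
    group = np.array([grouping[int(c)] for c in ald.cohort])
    return dataclasses.replace(ald, group=group)


@dataclass(frozen=True)
class OverlapStats:
    """Consecutive-wave person overlap, under two candidate definitions.

    ``consecutive`` counts interview participation (a person aged past
    the last design column still participated); ``consecutive_in_design``
    counts only waves contributing a design-grid observation.  The exact
    definition behind a survey's published mean overlap is often
    unstated, so both are reported.
    """

    #: (earlier, later wave) -> share of earlier-wave participants seen later.
    consecutive: dict[tuple[int, int], float]
    mean: float
    #: same shares restricted to the design grid.
    consecutive_in_design: dict[tuple[int, int], float]
    mean_in_design: float
    #: wave -> share of first-wave participants also seen at that wave.
    baseline_retention: dict[int, float]


def _pairwise(present: dict[int, np.ndarray], waves) -> tuple[dict, float]:
    out: dict[tuple[int, int], float] = {}
    for w1, w2 in zip(waves[:-1], waves[1:]):
        n1 = int(present[w1].sum())
        both = int((present[w1] & present[w2]).sum())
        out[(w1, w2)] = both / n1 if n1 else float("nan")
    return out, float(np.nanmean(list(out.values())))


def overlap_statistics(ald: ALDMatrix, schedule: DesignSchedule) -> OverlapStats:
    """Share of persons observed in consecutive wave pairs.

    Participation comes from ``wave_presence`` when the matrix was built
    by :func:`rearrange`; the in-design variant reconstructs presence
    from the observed time points via entry wave, cohort and offsets.
    Without ``wave_presence`` the in-design reconstruction serves both.
    """
    if len(schedule.wave_years) < 2:
        raise ValueError("need at least two waves")
    obs_t = ald.observed_timepoints()  # (n, T)
    entry_of_cohort = {b.cohort: b.entry_wave for b in schedule.cohort_bins}
    entry = np.array([entry_of_cohort[int(c)] for c in ald.cohort])

    in_design: dict[int, np.ndarray] = {}
    for w in schedule.wave_years:
        mask = np.zeros(ald.n_persons, dtype=bool)
        for e in schedule.entry_waves:
            offs = schedule.wave_column_offsets[e]
            if w not in offs:
                continue
            sel = entry == e
            base = schedule.anchor_cohorts[e] - ald.cohort[sel] + 1
            col = base + offs[w]
            ok = col <= schedule.n_columns
            idx = np.flatnonzero(sel)
            mask[idx[ok]] = obs_t[idx[ok], col[ok] - 1]
        in_design[w] = mask

    if ald.wave_presence is not None and ald.wave_years is not None:
        participate = {
            w: ald.wave_presence[:, k] for k, w in enumerate(ald.wave_years)
        }
    else:
        participate = in_design

    cons, mean = _pairwise(participate, list(schedule.wave_years))
    cons_d, mean_d = _pairwise(in_design, list(schedule.wave_years))

    w0 = schedule.wave_years[0]
    n0 = int(participate[w0].sum())
    baseline_retention = {
        int(w): (int((participate[w0] & participate[w]).sum()) / n0
                 if n0 else float("nan"))
        for w in schedule.wave_years[1:]
    }
    return OverlapStats(consecutive=cons, mean=mean,
                        consecutive_in_design=cons_d, mean_in_design=mean_d,
                        baseline_retention=baseline_retention)
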