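"""Post-fit trajectory description: per-class marker prevalences by age.

After the latent classes are estimated, each class is described by the
share of its households exhibiting each marker at each design time
point — the class's household-composition trajectory over the ~35-year
age window.  An overall (class-free) prevalence table in the same
layout serves as the descriptive marginal view of the accelerated
panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ITEM_NAMES, ALDMatrix, DesignSchedule
from .lca import FittedModel

WEIGHTINGS = ("modal", "posterior")


def marker_prevalence_by_timepoint(
    ald: ALDMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(prevalence, counts): item x time-point share of 'present' cells.

    Cells observed for nobody are NaN (not available), never 0.
    """
    if ald.n_persons == 0:
        raise ValueError("empty ALD matrix")
    num = (ald.values * ald.observed).sum(axis=0).astype(float)
    den = ald.observed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(den > 0, num / den, np.nan)
    idx = pd.Index(ITEM_NAMES[: ald.n_items], name="item")
    cols = pd.Index(range(1, ald.n_timepoints + 1), name="time_point")
    return (
        pd.DataFrame(prev, index=idx, columns=cols),
        pd.DataFrame(den.astype(int), index=idx, columns=cols),
    )


@dataclass
class ClassProfiles:
    """Per-class item x time-point prevalences with effective cell sizes."""

    prevalence: np.ndarray      # (S, n_items, n_timepoints), NaN where empty
    n_effective: np.ndarray     # same shape; posterior mass (or count) per cell
    weighting: str
    class_proportions: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.prevalence.shape[0]


def class_profiles(
    model: FittedModel, ald: ALDMatrix, weighting: str = "posterior"
) -> ClassProfiles:
    """Within-class observed-cell marker means.

    ``posterior`` weights each person's cells by their posterior class
    probability; ``modal`` uses hard assignment counts.  A class with no
    assigned members yields an all-NaN profile (flagged by n_effective 0).
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if model.posteriors.shape[0] != ald.n_persons:
        raise ValueError("model was not fitted on this ALD matrix")
    X, O = ald.flat()
    if weighting == "modal":
        modal = model.posteriors.argmax(axis=1)
        W = np.zeros_like(model.posteriors)
        W[np.arange(len(modal)), modal] = 1.0
    else:
        W = model.posteriors
    num = W.T @ X
    den = W.T @ O
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(den > 0, num / den, np.nan)
    shape = (model.n_classes, ald.n_items, ald.n_timepoints)
    return ClassProfiles(
        prevalence=prev.reshape(shape),
        n_effective=den.reshape(shape),
        weighting=weighting,
        class_proportions=model.params.class_proportions.copy(),
    )


def profile_report(
    profiles: ClassProfiles, schedule: DesignSchedule | None = None
) -> pd.DataFrame:
    """Tidy long-format export: one row per (class, item, time point).

    Unobserved cells appear as explicit rows with NaN prevalence so the
    full grid is preserved; mean ages come from the schedule's nominal
    column ages when a schedule is given.
    """
    S, n_items, n_t = profiles.prevalence.shape
    cls, item, t = np.meshgrid(
        np.arange(1, S + 1), np.arange(n_items), np.arange(1, n_t + 1),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "class": cls.ravel(),
            "item": np.array(ITEM_NAMES[:n_items])[item.ravel()],
            "time_point": t.ravel(),
            "prevalence": profiles.prevalence.ravel(),
            "n_effective": profiles.n_effective.ravel(),
        }
    )
    if schedule is not None and len(schedule.nominal_ages) == n_t:
        df.insert(3, "mean_age", np.asarray(schedule.nominal_ages)[df["time_point"] - 1])
    return df


def report_to_array(df: pd.DataFrame) -> np.ndarray:
    """Round-trip helper: rebuild the (S, items, timepoints) array from a
    tidy report."""
    S = int(df["class"].max())
    items = list(dict.fromkeys(df["item"]))
    n_t = int(df["time_point"].max())
    out = np.full((S, len(items), n_t), np.nan)
    pos = {name: i for i, name in enumerate(items)}
    for _, r in df.iterrows():
        out[int(r["class"]) - 1, pos[r["item"]], int(r["time_point"]) - 1] = r[
            "prevalence"
        ]
    return out


def plot_profiles(profiles: ClassProfiles, schedule: DesignSchedule, path) -> None:
    """Optional line-plot rendering (one panel per class) to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    S = profiles.n_classes
    ages = np.asarray(schedule.nominal_ages)
    fig, axes = plt.subplots(1, S, figsize=(4 * S, 3.2), sharey=True, squeeze=False)
    for s, ax in enumerate(axes[0]):
        for i, name in enumerate(ITEM_NAMES[: profiles.prevalence.shape[1]]):
            ax.plot(ages, profiles.prevalence[s, i], label=name, lw=1)
        ax.set_title(f"Class {s + 1} ({100 * profiles.class_proportions[s]:.0f}%)")
        ax.set_xlabel("age")
        ax.set_ylim(0, 1)
    axes[0, 0].set_ylabel("prevalence")
    axes[0, -1].legend(fontsize=6, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
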