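"""File I/O for panels, ALD arrays, fitted models and reports.

All writers go through an atomic write-then-rename so artifacts are
never left half-written.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ITEM_NAMES, MARKER_COLUMNS, PANEL_COLUMNS, ALDMatrix
from .lca import MGLCAParams

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


def atomic_write(path, data: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_panel(path) -> pd.DataFrame:
    """Read a long-format panel CSV (person_id, wave_year, age, sex,
    marker_1..marker_9 with 0/1 values).

    Rows with malformed ages or non-binary item values are rejected with
    line-numbered diagnostics (logged); missing columns or an empty file
    raise :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    ok = np.ones(len(df), dtype=bool)
    reasons: list[tuple[int, str]] = []

    age = pd.to_numeric(df["age"], errors="coerce")
    bad = age.isna() | (age < 0) | (age != age.round())
    for idx in np.flatnonzero(bad):
        reasons.append((idx + 2, f"malformed age {df['age'].iloc[idx]!r}"))
    ok &= ~bad.to_numpy()

    for col in ["sex"] + MARKER_COLUMNS:
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | ~v.isin([0, 1])
        for idx in np.flatnonzero(bad & ok):
            reasons.append((idx + 2, f"non-binary {col} value {df[col].iloc[idx]!r}"))
        ok &= ~bad.to_numpy()

    if reasons:
        for line, why in reasons[:20]:
            logger.warning("%s line %d: %s (row rejected)", path, line, why)
        logger.warning("%s: rejected %d malformed rows", path, len(reasons))
    out = df[ok].copy()
    out["age"] = out["age"].astype(int)
    out["wave_year"] = out["wave_year"].astype(int)
    for col in ["sex"] + MARKER_COLUMNS:
        out[col] = out[col].astype(np.uint8)
    return out.reset_index(drop=True)


def write_ald_csv(ald: ALDMatrix, path) -> None:
    """Wide CSV: person_id, cohort, group, then item{i}_t{t} columns with
    empty cells where unobserved."""
    cols = {}
    cols["person_id"] = ald.person_id
    cols["cohort"] = ald.cohort
    cols["group"] = ald.group if ald.group is not None else [""] * ald.n_persons
    for i in range(ald.n_items):
        for t in range(ald.n_timepoints):
            v = ald.values[:, i, t].astype(float)
            v[~ald.observed[:, i, t]] = np.nan
            cols[f"item{i + 1}_t{t + 1}"] = v
    df = pd.DataFrame(cols)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    df.to_csv(tmp, index=False, float_format="%.0f")
    os.replace(tmp, path)


def read_ald_csv(path) -> ALDMatrix:
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise SchemaError(f"{path}: missing person_id column")
    item_cols = [c for c in df.columns if c.startswith("item") and "_t" in c]
    if not item_cols:
        raise SchemaError(f"{path}: no item{{i}}_t{{t}} columns")
    n_items = max(int(c.split("_t")[0][4:]) for c in item_cols)
    n_t = max(int(c.split("_t")[1]) for c in item_cols)
    n = len(df)
    values = np.zeros((n, n_items, n_t), dtype=np.uint8)
    observed = np.zeros((n, n_items, n_t), dtype=bool)
    for c in item_cols:
        i = int(c.split("_t")[0][4:]) - 1
        t = int(c.split("_t")[1]) - 1
        v = pd.to_numeric(df[c], errors="coerce")
        observed[:, i, t] = v.notna()
        values[v.notna(), i, t] = v.dropna().astype(np.uint8)
    group = None
    if "group" in df.columns and df["group"].notna().any():
        group = df["group"].fillna("").to_numpy()
    return ALDMatrix(
        values=values,
        observed=observed,
        person_id=df["person_id"].to_numpy(),
        cohort=df["cohort"].to_numpy(dtype=int) if "cohort" in df.columns
        else np.zeros(n, dtype=int),
        group=group,
    )


def missingness_summary(ald: ALDMatrix) -> dict:
    obs = ald.observed
    per_tp = obs.any(axis=1).sum(axis=0)
    return {
        "n_persons": int(ald.n_persons),
        "n_items": int(ald.n_items),
        "n_timepoints": int(ald.n_timepoints),
        "n_observed_cells": int(obs.sum()),
        "share_cells_observed": float(obs.mean()),
        "persons_per_timepoint": [int(k) for k in per_tp],
        "cells_never_observed": int((~obs.any(axis=0)).sum()),
    }


def model_to_dict(model) -> dict:
    return {
        "n_classes": int(model.n_classes),
        "class_proportions": model.params.class_proportions.tolist(),
        "item_probs": model.params.item_probs.tolist(),
        "loglik": float(model.loglik),
        "n_obs_used": int(model.n_obs_used),
        "converged": bool(model.converged),
        "n_iterations": int(model.n_iterations),
        "n_starts": int(model.n_starts),
        "best_start": int(model.best_start),
    }


def write_model_json(model, path, settings: dict | None = None) -> None:
    doc = model_to_dict(model)
    if settings:
        doc["settings"] = settings
    atomic_write(path, json.dumps(doc, indent=1, sort_keys=True))


def read_model_json(path) -> tuple[MGLCAParams, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    params = MGLCAParams(
        np.asarray(doc["class_proportions"], float),
        np.asarray(doc["item_probs"], float),
    )
    return params, doc


def write_posteriors_csv(model, person_id, path) -> None:
    post = model.posteriors
    df = pd.DataFrame(
        post, columns=[f"class_{s + 1}" for s in range(post.shape[1])]
    )
    df.insert(0, "person_id", person_id)
    df["modal_class"] = post.argmax(axis=1) + 1
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    df.to_csv(tmp, index=False, float_format="%.6f")
    os.replace(tmp, path)
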