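"""End-to-end run configuration and orchestration.

A run is: (optionally) simulate a panel -> rearrange it into the
accelerated layout -> tabulate counts -> fit the invariant latent class
model for each candidate class count -> build the enumeration table ->
profile the selected classes.  Every stochastic stage draws its seed
deterministically from the single root seed, and a manifest records the
hash of every artifact, so identical configs reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .design import DEFAULT_GROUPING, count_tables, group_cohorts, mhas_schedule, overlap_statistics, rearrange
from .profiles import class_profiles, marker_prevalence_by_timepoint, profile_report
from .selection import enumerate_classes, format_selection_table
from .synthetic import SyntheticConfig, generate_population

logger = logging.getLogger("aldlca.pipeline")


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    out_dir: Path
    seed: int
    panel_path: Path | None = None          # either a panel CSV ...
    synthetic: SyntheticConfig | None = None  # ... or synthetic conditions
    s_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    n_starts: int = 20
    tol: float = 1e-6
    max_iter: int = 1000
    grouping: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    profile_weighting: str = "posterior"

    def __post_init__(self) -> None:
        if (self.panel_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of panel_path / synthetic")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise ValueError(f"panel not found: {self.panel_path}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        syn = None
        if "synthetic" in doc:
            syn_doc = dict(doc["synthetic"])
            for key in ("class_proportions", "sex_probs", "wave_years",
                        "birth_year_range", "refresh_birth_year_range",
                        "attrition_hazard"):
                if key in syn_doc:
                    syn_doc[key] = tuple(syn_doc[key])
            syn = SyntheticConfig(**syn_doc)
        grouping = {int(k): str(v) for k, v in doc.get("grouping", {}).items()} \
            or dict(DEFAULT_GROUPING)
        return cls(
            out_dir=Path(doc["out_dir"]),
            seed=int(doc["seed"]),
            panel_path=Path(doc["panel"]) if "panel" in doc else None,
            synthetic=syn,
            s_range=list(doc.get("s_range", [1, 2, 3, 4])),
            n_starts=int(doc.get("n_starts", 20)),
            tol=float(doc.get("tol", 1e-6)),
            max_iter=int(doc.get("max_iter", 1000)),
            grouping=grouping,
            profile_weighting=str(doc.get("profile_weighting", "posterior")),
        )


def derive_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the single root seed."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure propagates with the stage name in the log; the
    artifacts of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = mhas_schedule()
    artifacts: dict[str, str] = {}

    stage = "simulate"
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(
                config.synthetic, seed=derive_seed(config.seed, "simulate")
            )
            logger.info("[simulate] n=%d+%d persons, %d classes",
                        syn.n_baseline, syn.n_refresh, syn.s_true)
            pop = generate_population(syn, schedule)
            panel = pop.panel
            panel.to_csv(out / "panel.csv", index=False)
            pop.true_class.reset_index().to_csv(out / "truth.csv", index=False)
            artifacts["panel.csv"] = _sha256(out / "panel.csv")
            artifacts["truth.csv"] = _sha256(out / "truth.csv")
        else:
            logger.info("[read] %s", config.panel_path)
            panel = aio.read_panel(config.panel_path)

        stage = "rearrange"
        logger.info("[rearrange] %d records", len(panel))
        ald = rearrange(panel, schedule)
        ald = group_cohorts(ald, config.grouping)
        aio.write_ald_csv(ald, out / "ald.csv")
        aio.atomic_write(out / "missingness.json",
                         json.dumps(aio.missingness_summary(ald), indent=1))
        artifacts["ald.csv"] = _sha256(out / "ald.csv")
        artifacts["missingness.json"] = _sha256(out / "missingness.json")

        stage = "tabulate"
        wave_tab, cohort_tab = count_tables(panel, schedule)
        wave_tab.to_csv(out / "table_wave_by_column.csv")
        cohort_tab.to_csv(out / "table_cohort_by_column.csv")
        artifacts["table_wave_by_column.csv"] = _sha256(out / "table_wave_by_column.csv")
        artifacts["table_cohort_by_column.csv"] = _sha256(
            out / "table_cohort_by_column.csv")
        overlap = overlap_statistics(ald, schedule)
        aio.atomic_write(
            out / "overlap.json",
            json.dumps(
                {
                    "consecutive": {f"{a}-{b}": v
                                    for (a, b), v in overlap.consecutive.items()},
                    "mean": overlap.mean,
                    "consecutive_in_design": {
                        f"{a}-{b}": v
                        for (a, b), v in overlap.consecutive_in_design.items()
                    },
                    "mean_in_design": overlap.mean_in_design,
                    "baseline_retention": overlap.baseline_retention,
                },
                indent=1,
            ),
        )
        artifacts["overlap.json"] = _sha256(out / "overlap.json")

        stage = "select"
        logger.info("[select] S in %s", config.s_range)
        result = enumerate_classes(
            ald, config.s_range,
            n_starts=config.n_starts, tol=config.tol, max_iter=config.max_iter,
            seed=derive_seed(config.seed, "fit"),
        )
        for S, model in result.models.items():
            aio.write_model_json(
                model, out / f"model_S{S}.json",
                settings={"n_starts": config.n_starts, "tol": config.tol,
                          "max_iter": config.max_iter,
                          "seed": derive_seed(config.seed, "fit")},
            )
            artifacts[f"model_S{S}.json"] = _sha256(out / f"model_S{S}.json")
        result.to_frame().to_csv(out / "selection.csv", index=False)
        aio.atomic_write(out / "selection.md", format_selection_table(result))
        artifacts["selection.csv"] = _sha256(out / "selection.csv")
        artifacts["selection.md"] = _sha256(out / "selection.md")

        stage = "profile"
        best = result.models[result.best_bic_S]
        aio.write_posteriors_csv(best, ald.person_id, out / "posteriors.csv")
        artifacts["posteriors.csv"] = _sha256(out / "posteriors.csv")
        prev, counts = marker_prevalence_by_timepoint(ald)
        prev.to_csv(out / "marker_prevalence.csv")
        artifacts["marker_prevalence.csv"] = _sha256(out / "marker_prevalence.csv")
        prof = class_profiles(best, ald, config.profile_weighting)
        report = profile_report(prof, schedule)
        report.to_csv(out / "profiles.csv", index=False)
        artifacts["profiles.csv"] = _sha256(out / "profiles.csv")
    except Exception:
        logger.error("pipeline failed in stage [%s]", stage)
        raise

    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in ("simulate", "fit")},
        "s_range": list(config.s_range),
        "selected_S_by_bic": result.best_bic_S,
        "artifacts": artifacts,
    }
    aio.atomic_write(out / "manifest.json", json.dumps(manifest, indent=1,
                                                       sort_keys=True))
    return manifest
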