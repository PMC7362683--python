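"""Class-enumeration statistics: -2logL, BIC, relative entropy, class sizes.

The number of latent trajectory classes is unknown, so models with an
increasing number of classes are fitted and compared.  Following common
practice for this design the comparison table reports, per class count
S: the -2 log-likelihood, the BIC (lower is better), the relative
entropy of the posterior classification (1 = perfect separation), the
range of relative class sizes, and the range across classes of the
average posterior probability among assigned members.  Likelihood-ratio
style tests (e.g. Lo-Mendell-Rubin) are deliberately not computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ALDMatrix
from .lca import FittedModel, classify, fit

PARAM_MODES = ("all-cells", "observed-cells")


def count_parameters(S: int, ald: ALDMatrix, mode: str = "all-cells") -> int:
    """Free-parameter count of the fully invariant S-class model.

    ``all-cells``: (S-1) mixing proportions plus one threshold per class
    and per item x time-point cell of the design grid.  ``observed-cells``
    counts only cells observed for at least one person (the others are
    never updated by the data).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if mode not in PARAM_MODES:
        raise ValueError(f"mode must be one of {PARAM_MODES}")
    if mode == "all-cells":
        n_cells = ald.n_cells
    else:
        n_cells = int(ald.observed.any(axis=0).sum())
    return (S - 1) + S * n_cells


def bic(minus2_loglik: float, n_params: int, n: int) -> float:
    """Schwarz criterion: -2logL + n_params * ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(minus2_loglik + n_params * np.log(n))


def relative_entropy(posteriors: np.ndarray) -> float:
    """Rescaled classification entropy, 1 - sum(-p ln p) / (N ln S).

    1 means every person is classified with certainty, 0 means the
    posteriors are uniform.  Undefined for a single class (S = 1);
    callers print a dash there.
    """
    post = np.asarray(posteriors, float)
    N, S = post.shape
    if S < 2:
        raise ValueError("relative entropy needs S >= 2")
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    ent = -plogp.sum()
    return float(1.0 - ent / (N * np.log(S)))


@dataclass
class SelectionRow:
    """One row of the class-enumeration table."""

    S: int
    minus2_loglik: float
    n_params: int                   # all-cells count (used in the BIC column)
    n_params_observed: int
    bic: float
    bic_observed: float
    entropy: float | None           # None for S = 1
    class_size_min_pct: float | None
    class_size_max_pct: float | None
    posterior_min: float | None     # min/max across classes of the mean
    posterior_max: float | None     # assigned posterior
    converged: bool


@dataclass
class SelectionResult:
    rows: list[SelectionRow]
    models: dict[int, FittedModel]
    best_bic_S: int
    best_entropy_S: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _derive_seed(seed: int, S: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(S)]).generate_state(1)[0]
               % (2**31))


def enumerate_classes(
    ald: ALDMatrix,
    s_range: list[int] | range,
    *,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    param_mode: str = "all-cells",
) -> SelectionResult:
    """Fit every S in ``s_range`` and build the enumeration table.

    All fits share the EM settings; each S gets a seed derived
    deterministically from (seed, S).  A fit that fails to converge is
    reported with ``converged=False`` rather than aborting the table.
    """
    s_list = list(s_range)
    if not s_list or s_list != sorted(s_list):
        raise ValueError("s_range must be non-empty and ascending")
    rows: list[SelectionRow] = []
    models: dict[int, FittedModel] = {}
    for S in s_list:
        model = fit(ald, S, n_starts=n_starts, tol=tol, max_iter=max_iter,
                    seed=_derive_seed(seed, S))
        models[S] = model
        m2ll = -2.0 * model.loglik
        p_all = count_parameters(S, ald, "all-cells")
        p_obs = count_parameters(S, ald, "observed-cells")
        used = ald.observed.any(axis=(1, 2))
        post_used = model.posteriors[used]
        if S >= 2:
            ent = relative_entropy(post_used)
            cls = classify(model)
            shares = cls.table["share_pct"]
            pmeans = cls.table["p_mean"]
            row = SelectionRow(
                S, m2ll, p_all, p_obs,
                bic(m2ll, p_all, model.n_obs_used),
                bic(m2ll, p_obs, model.n_obs_used),
                ent,
                float(shares.min()), float(shares.max()),
                float(pmeans.min()), float(pmeans.max()),
                model.converged,
            )
        else:
            row = SelectionRow(
                S, m2ll, p_all, p_obs,
                bic(m2ll, p_all, model.n_obs_used),
                bic(m2ll, p_obs, model.n_obs_used),
                None, None, None, None, None, model.converged,
            )
        rows.append(row)

    key = "bic" if param_mode == "all-cells" else "bic_observed"
    best_bic_S = min(rows, key=lambda r: getattr(r, key)).S
    with_ent = [r for r in rows if r.entropy is not None]
    best_entropy_S = max(with_ent, key=lambda r: r.entropy).S if with_ent else None
    return SelectionResult(rows, models, best_bic_S, best_entropy_S)


def format_selection_table(result: SelectionResult) -> str:
    """Markdown rendering with the conventional six columns:
    (1) class count, (2) -2logL, (3) BIC, (4) entropy,
    (5) relative class size range, (6) range of probabilities."""
    header = (
        "| Class | -2xlog-L | BIC | Entropy | Relative class size (%) | "
        "Range of probabilities |"
    )
    sep = "|---|---|---|---|---|---|"
    lines = [header, sep]
    for r in result.rows:
        if r.entropy is None:
            ent = size = rng = "-"
        else:
            ent = f"{r.entropy:.3f}"
            size = f"{r.class_size_min_pct:.0f} - {r.class_size_max_pct:.0f}"
            rng = f"{r.posterior_min:.3f} - {r.posterior_max:.3f}"
        mark = "" if r.converged else " (not converged)"
        lines.append(
            f"| {r.S}{mark} | {r.minus2_loglik:,.0f} | {r.bic:,.0f} | "
            f"{ent} | {size} | {rng} |"
        )
    lines.append("")
    lines.append(
        f"BIC-minimizing S = {result.best_bic_S}; "
        f"entropy-maximizing S = {result.best_entropy_S}"
    )
    return "\n".join(lines)
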