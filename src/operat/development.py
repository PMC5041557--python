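"""Structure-finding pipeline: item screening and iterative EFA refinement.

Pilot audit items are first screened against resident validation-survey
responses with Kendall's tau-b (p < 0.05, with expert overrides and an item
collapsing map), then the retained item matrix is factor-analysed.  Model
refinement removes one item at a time -- the item with the smallest maximum
absolute loading, whenever that value falls below 0.4 -- and re-estimates
after each deletion until every retained item loads at 0.4 or more.  The
number of factors is chosen by the eigenvalue >= 1 rule plus fit-index
adequacy, guarded by interpretability: a solution in which some factor holds
fewer than two salient items is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .factor import (
    ConvergenceError,
    FitIndices,
    geomin_rotate,
    ml_fit_indices,
    principal_axis_factoring,
)
from .instrument import AreaAssessment, InstrumentSpec
from .scoring import recode_item

__all__ = [
    "ValidationScreenResult",
    "FactorModel",
    "kendall_tau_b",
    "screen_items",
    "efa_matrix",
    "fit_efa",
    "refine_model",
]


@dataclass(frozen=True)
class ValidationScreenResult:
    """Outcome of screening one pilot item against its validation question."""

    item_id: str
    tau_b: float
    p_value: float
    retained: bool
    retained_reason: str  # significant | expert_override | collapsed_into:<id> | dropped


@dataclass
class FactorModel:
    """An exploratory factor solution with its fit and refinement history."""

    n_factors: int
    loadings: pd.DataFrame  # item x factor pattern matrix
    phi: np.ndarray  # factor correlation matrix
    eigenvalues: np.ndarray  # of the item correlation matrix
    fit: FitIndices
    retained_items: list[str]
    dropped_items: list[tuple[str, int, float]] = field(default_factory=list)
    n_obs: int = 0

    def salient_items(self, factor: int, threshold: float = 0.4) -> list[str]:
        """Items whose largest absolute loading sits on ``factor`` at >= threshold."""
        L = self.loadings.to_numpy()
        out = []
        for i, item in enumerate(self.loadings.index):
            j = int(np.abs(L[i]).argmax())
            if j == factor and abs(L[i, j]) >= threshold:
                out.append(item)
        return out

    def summary(self, blank_below: float = 0.4) -> pd.DataFrame:
        """Human-readable pattern matrix with sub-threshold loadings blanked."""
        L = self.loadings.round(2)
        return L.where(L.abs() >= blank_below, "")


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a normal-approximation p-value.

    Missing values (NaN) are deleted pairwise; at least three complete pairs
    are required and neither margin may be constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined: one variable is constant")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def screen_items(
    pilot_items: Sequence[str],
    assessment_data: pd.DataFrame,
    validation_data: pd.DataFrame,
    pairing: Mapping[str, str],
    *,
    overrides: Sequence[str] = (),
    collapse: Optional[Mapping[str, Sequence[str]]] = None,
    alpha: float = 0.05,
) -> tuple[list[ValidationScreenResult], pd.DataFrame]:
    """Screen pilot items against resident perceptions.

    Each respondent row of ``validation_data`` (indexed by ``area_id`` column)
    is paired with their area's value of the corresponding pilot item
    (``pairing`` maps item_id -> validation column).  An item is retained when
    its tau-b is significant at ``alpha`` or it appears in ``overrides``.
    ``collapse`` maps a new composite item_id to the retained source items it
    replaces (combined by their mean); applied after screening.

    Returns the per-item screen results and the post-collapse item matrix
    (areas x retained items) ready for EFA.
    """
    if "area_id" not in assessment_data.columns:
        raise ValueError("assessment_data needs an area_id column")
    if "area_id" not in validation_data.columns:
        raise ValueError("validation_data needs an area_id column")
    linked = validation_data["area_id"].isin(set(assessment_data["area_id"]))
    if not linked.any():
        raise ValueError(
            f"no validation respondents link to assessed areas "
            f"(0 of {len(validation_data)})"
        )
    vdata = validation_data[linked]
    area_rows = assessment_data.set_index("area_id")

    results: list[ValidationScreenResult] = []
    retained: list[str] = []
    for item in pilot_items:
        vcol = pairing.get(item)
        if vcol is None or vcol not in vdata.columns:
            raise KeyError(f"no validation pairing for pilot item {item!r}")
        item_vals = area_rows.loc[vdata["area_id"], item].to_numpy(dtype=float)
        resp_vals = vdata[vcol].to_numpy(dtype=float)
        tau, p = kendall_tau_b(item_vals, resp_vals)
        if p < alpha:
            reason, keep = "significant", True
        elif item in overrides:
            reason, keep = "expert_override", True
        else:
            reason, keep = "dropped", False
        results.append(ValidationScreenResult(item, tau, p, keep, reason))
        if keep:
            retained.append(item)

    matrix = area_rows[retained].copy()
    if collapse:
        for new_id, sources in collapse.items():
            present = [s for s in sources if s in matrix.columns]
            if not present:
                continue
            matrix[new_id] = matrix[present].mean(axis=1)
            matrix = matrix.drop(columns=present)
            for s in present:
                idx = next(i for i, r in enumerate(results) if r.item_id == s)
                r = results[idx]
                results[idx] = ValidationScreenResult(
                    r.item_id, r.tau_b, r.p_value, True, f"collapsed_into:{new_id}"
                )
    return results, matrix.reset_index()


def efa_matrix(spec: InstrumentSpec, assessments: Sequence[AreaAssessment]) -> pd.DataFrame:
    """Item matrix in the form used for factor analysis.

    Proportion items enter in their original form; binary and ordinal items
    are recoded onto the 0 = best / 1 = worst scale.
    """
    rows = []
    for a in assessments:
        row: dict[str, float] = {}
        for it in spec.items:
            v = a.observations[it.item_id]
            row[it.item_id] = (
                float(v) if it.value_kind == "proportion" else recode_item(it, v)
            )
        rows.append(row)
    return pd.DataFrame(rows, index=[a.area_id for a in assessments])


def fit_efa(
    data: pd.DataFrame,
    n_factors: int,
    *,
    rotation_seed: int = 0,
    geomin_eps: float = 0.01,
) -> FactorModel:
    """Fit one exploratory factor model to an area x item matrix.

    Extraction is principal axis factoring on the Pearson correlation matrix;
    the pattern matrix is obliquely Geomin-rotated; fit indices come from a
    parallel ML fit at the same dimensionality.  Rows with missing values are
    dropped (complete-case analysis).
    """
    data = data.dropna()
    n, p = data.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than items ({p})")
    R = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix undefined: a column is constant")
    A, eigenvalues = principal_axis_factoring(R, n_factors)
    L, phi = geomin_rotate(A, eps=geomin_eps, seed=rotation_seed)
    fit = ml_fit_indices(R, n_factors, n)
    loadings = pd.DataFrame(
        L, index=list(data.columns), columns=[f"F{j + 1}" for j in range(n_factors)]
    )
    return FactorModel(
        n_factors=n_factors,
        loadings=loadings,
        phi=phi,
        eigenvalues=eigenvalues,
        fit=fit,
        retained_items=list(data.columns),
        n_obs=n,
    )


def _passes_interpretability(model: FactorModel, threshold: float = 0.4) -> bool:
    """Every factor must hold at least two salient items."""
    return all(
        len(model.salient_items(j, threshold)) >= 2 for j in range(model.n_factors)
    )


def refine_model(
    data: pd.DataFrame,
    start_items: Sequence[str],
    candidate_factors: Iterable[int],
    *,
    loading_threshold: float = 0.4,
    rmsea_adequate: float = 0.08,
    cfi_adequate: float = 0.95,
    rotation_seed: int = 0,
) -> FactorModel:
    """Iterative EFA refinement with factor-count selection.

    Stage 1 fits every candidate factor count to the full start item set (the
    fit grid); the count is selected among candidates that pass the
    interpretability guard (every factor holds at least two salient items --
    the reason a five-factor solution loses to a four-factor one when its
    extra factor comprises a single item) by preferring adequate fit
    (RMSEA <= ``rmsea_adequate`` and CFI >= ``cfi_adequate``), agreement with
    the eigenvalue >= 1 count, then parsimony.  Stage 2 runs the low-loading
    deletion loop at the selected count: the single item with the smallest
    maximum absolute loading is removed whenever that value is below
    ``loading_threshold``, and the model is re-estimated after each deletion
    until a fixed point.
    """
    missing_cols = [c for c in start_items if c not in data.columns]
    if missing_cols:
        raise KeyError(f"start_items not in data: {missing_cols}")
    candidates = sorted(set(candidate_factors))
    if not candidates:
        raise ValueError("candidate_factors is empty")

    grid: dict[int, FactorModel] = {}
    failed: dict[int, str] = {}
    for k in candidates:
        try:
            grid[k] = fit_efa(data[list(start_items)], k, rotation_seed=rotation_seed)
        except (ConvergenceError, ValueError) as exc:
            failed[k] = str(exc)
    if not grid:
        raise ValueError(f"every candidate factor count failed: {failed}")

    n_eigen = int(np.sum(next(iter(grid.values())).eigenvalues >= 1.0))

    def adequate(m: FactorModel) -> bool:
        return m.fit.rmsea <= rmsea_adequate and m.fit.cfi >= cfi_adequate

    interpretable = [
        k for k in sorted(grid) if _passes_interpretability(grid[k], loading_threshold)
    ]
    if not interpretable:
        raise ValueError("no candidate factor count yields an interpretable model")
    good = [k for k in interpretable if adequate(grid[k])]
    if good:
        eigen_good = [k for k in good if k == n_eigen]
        chosen = eigen_good[0] if eigen_good else min(good)
    else:
        chosen = min(interpretable, key=lambda k: grid[k].fit.rmsea)

    dropped: list[tuple[str, int, float]] = []
    model = _deletion_loop(
        data, list(start_items), chosen, dropped, loading_threshold, rotation_seed
    )
    model.dropped_items = dropped
    if not _passes_interpretability(model, loading_threshold):
        raise ValueError(
            f"refinement at {chosen} factors emptied a factor (degenerate model)"
        )
    return model


def _deletion_loop(
    data: pd.DataFrame,
    items: list[str],
    k: int,
    dropped: list[tuple[str, int, float]],
    loading_threshold: float,
    rotation_seed: int,
) -> FactorModel:
    """Remove the weakest-loading item one at a time until all load >= 0.4."""
    model = None
    for iteration in range(len(items)):
        model = fit_efa(data[items], k, rotation_seed=rotation_seed)
        L = model.loadings.to_numpy()
        max_abs = np.abs(L).max(axis=1)
        worst = float(max_abs.min())
        if worst >= loading_threshold:
            break
        # smallest max |loading|; ties break lexicographically by item_id
        ties = [items[i] for i in range(len(items)) if max_abs[i] == worst]
        victim = min(ties)
        if len(items) - 1 <= k:
            raise ValueError(
                f"refinement at {k} factors removed too many items "
                f"(degenerate model)"
            )
        dropped.append((victim, iteration, worst))
        items.remove(victim)
    assert model is not None
    return model
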