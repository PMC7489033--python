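"""Maximum-likelihood estimation of the annual severity transition matrix.

For a discrete-time Markov chain observed as independent one-step pairs,
the MLE of each transition probability is the count ratio

    p_ij = n_ij / n_i,      n_i = sum_j n_ij,

i.e. row-wise multinomial proportions.  Per-cell 95% confidence bounds use
the normal (Wald) approximation p +/- z * sqrt(p(1-p)/n_i) by default, with
exact Clopper-Pearson bounds available as an alternative.  Bound matrices
are clamped to [0, 1]; their rows need not sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError
from .ingest import STATES, SeverityState

__all__ = [
    "TransitionModel",
    "StructuralReport",
    "count_transitions",
    "estimate_mle",
    "confidence_bounds",
    "classify_states",
    "fit_transition_model",
]

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionModel:
    """Counts, MLE point estimates and 95% bound matrices."""

    counts: np.ndarray
    point: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    row_totals: np.ndarray

    def __post_init__(self) -> None:
        for i, total in enumerate(self.row_totals):
            if total > 0 and abs(self.point[i].sum() - 1.0) > 1e-12:
                raise ValueError(f"point row {i} does not sum to 1")
        finite = ~np.isnan(self.lower95)
        if not (
            (self.lower95[finite] <= self.point[finite] + 1e-15).all()
            and (self.point[finite] <= self.upper95[finite] + 1e-15).all()
        ):
            raise ValueError("bounds do not bracket the point estimates")


@dataclass(frozen=True)
class StructuralReport:
    """Structural diagnostics of an estimated chain."""

    absorbing: tuple[bool, bool, bool]
    steady_state_reached: bool
    horizon: int
    tolerance: float
    final_max_change: float


def count_transitions(
    pairs: Iterable[tuple[SeverityState, SeverityState]],
) -> np.ndarray:
    """Tally (from-state, to-state) pairs into a 3x3 integer count matrix."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for from_state, to_state in pairs:
        counts[int(from_state), int(to_state)] += 1
    return counts


def estimate_mle(
    counts: np.ndarray,
    empty_row: Literal["self_loop", "error"] = "self_loop",
) -> np.ndarray:
    """Row-wise multinomial MLE, p_ij = n_ij / n_i.

    A row with no observed transitions has an undefined MLE; by default it
    is set to the degenerate self-loop (p_ii = 1) with a warning so that
    projection stays well-defined on small fixtures.  Pass
    ``empty_row="error"`` to raise instead.
    """
    counts = np.asarray(counts)
    if counts.shape != (3, 3) or (counts < 0).any():
        raise DomainError("counts must be a non-negative 3x3 matrix")
    row_totals = counts.sum(axis=1)
    if row_totals.sum() == 0:
        raise EstimationError("no transitions observed; cannot estimate")
    point = np.zeros((3, 3), dtype=float)
    for i, total in enumerate(row_totals):
        if total > 0:
            point[i] = counts[i] / total
        elif empty_row == "self_loop":
            logger.warning(
                "no transitions observed from state %s; using self-loop row",
                STATES[i].label,
            )
            point[i, i] = 1.0
        else:
            raise EstimationError(f"no transitions observed from state {STATES[i].label}")
    return point


def confidence_bounds(
    counts: np.ndarray,
    level: float = 0.95,
    method: Literal["normal", "clopper-pearson"] = "normal",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell confidence bounds for the transition probabilities.

    ``normal`` uses the Wald interval p +/- z*sqrt(p(1-p)/n_i) clamped to
    [0, 1]; ``clopper-pearson`` inverts the binomial CDF (exact, per cell).
    Rows without observations get NaN bounds.
    """
    if not 0.0 < level < 1.0:
        raise DomainError("confidence level must lie in (0, 1)")
    counts = np.asarray(counts)
    row_totals = counts.sum(axis=1)
    lower = np.full((3, 3), np.nan)
    upper = np.full((3, 3), np.nan)
    alpha = 1.0 - level
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        for i, total in enumerate(row_totals):
            if total == 0:
                continue
            p = counts[i] / total
            half = z * np.sqrt(p * (1.0 - p) / total)
            lower[i] = np.clip(p - half, 0.0, 1.0)
            upper[i] = np.clip(p + half, 0.0, 1.0)
    elif method == "clopper-pearson":
        for i, total in enumerate(row_totals):
            if total == 0:
                continue
            for j in range(3):
                k = counts[i, j]
                lower[i, j] = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, total - k + 1)
                upper[i, j] = (
                    1.0 if k == total else stats.beta.ppf(1 - alpha / 2, k + 1, total - k)
                )
    else:
        raise DomainError(f"unknown CI method {method!r}")
    return lower, upper


def fit_transition_model(
    pairs: Iterable[tuple[SeverityState, SeverityState]],
    level: float = 0.95,
    ci_method: Literal["normal", "clopper-pearson"] = "normal",
    empty_row: Literal["self_loop", "error"] = "self_loop",
) -> TransitionModel:
    """Count, estimate and bound in one step."""
    counts = count_transitions(pairs)
    point = estimate_mle(counts, empty_row=empty_row)
    lower, upper = confidence_bounds(counts, level=level, method=ci_method)
    # Degenerate self-loop rows have no data; their point is a convention,
    # so bracket it trivially to keep the model invariant satisfied.
    for i, total in enumerate(counts.sum(axis=1)):
        if total == 0:
            lower[i] = np.nan
            upper[i] = np.nan
    return TransitionModel(
        counts=counts,
        point=point,
        lower95=lower,
        upper95=upper,
        row_totals=counts.sum(axis=1),
    )


def _check_stochastic(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or (matrix < 0).any():
        raise DomainError("matrix must be non-negative 3x3")
    if np.abs(matrix.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
        raise DomainError("matrix rows must sum to 1")
    return matrix


def classify_states(
    point: np.ndarray,
    horizon: int = 10,
    tolerance: float = 1e-9,
    initial_occupancy: Sequence[float] = (784.0, 413.0, 144.0),
) -> StructuralReport:
    """Report absorbing states and horizon-bounded stationarity.

    A state is absorbing when its self-transition probability is exactly 1.
    "Steady state reached" means the occupancy distribution changes by less
    than ``tolerance`` (max-norm) between two successive years within the
    simulation horizon — a horizon-bounded statement, not a claim about the
    chain's limiting distribution.
    """
    matrix = _check_stochastic(point)
    absorbing = tuple(bool(matrix[i, i] == 1.0) for i in range(3))
    occupancy = np.asarray(initial_occupancy, dtype=float)
    occupancy = occupancy / occupancy.sum()
    reached = False
    max_change = np.inf
    for _ in range(1, horizon):
        nxt = occupancy @ matrix
        max_change = float(np.abs(nxt - occupancy).max())
        occupancy = nxt
        if max_change < tolerance:
            reached = True
            break
    return StructuralReport(
        absorbing=absorbing,  # type: ignore[arg-type]
        steady_state_reached=reached,
        horizon=horizon,
        tolerance=tolerance,
        final_max_change=max_change,
    )
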