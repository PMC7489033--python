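"""One-way sensitivity analysis of first-year total cost.

Each cost component aggregate (treatment, long-term care benefit, indirect
cost) is varied by +/- a fraction (default 50%) while the other two are
held fixed, and the first-year total cost is recomputed.  Holding the
others fixed matters: if indirect cost were re-derived as informal minus
benefit while the benefit varies, the benefit would cancel out of the
total and its bar would vanish — the components are treated as independent
inputs here.  Results are ranked by outcome range into a tornado table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .costs import CostSchedule
from .errors import ConfigurationError, DomainError
from .ingest import STATES

__all__ = [
    "SensitivityResult",
    "one_way_sensitivity",
    "tornado_table",
    "tornado_plot",
    "SENSITIVITY_PARAMETERS",
]

#: Cost components that can be varied, keyed by schedule attribute.
SENSITIVITY_PARAMETERS = ("treatment_annual", "benefit_annual", "indirect_annual")

_ATTR_BY_PARAM = {
    "treatment_annual": "treatment",
    "benefit_annual": "benefit",
    "indirect_annual": "indirect",
}


@dataclass(frozen=True)
class SensitivityResult:
    """Outcome range of one parameter's +/- variation."""

    parameter: str
    low_value: float  # multiplier applied at the low end, e.g. 0.5
    high_value: float  # multiplier at the high end, e.g. 1.5
    outcome_low: float  # EUR, first-year total cost at the low setting
    outcome_high: float
    range: float

    def __post_init__(self) -> None:
        if abs(self.range - abs(self.outcome_high - self.outcome_low)) > 1e-6:
            raise ValueError("range must equal |outcome_high - outcome_low|")


def _component_vectors(schedule: CostSchedule) -> dict[str, np.ndarray]:
    return {
        name: np.array([float(getattr(schedule, attr)[s]) for s in STATES])
        for name, attr in _ATTR_BY_PARAM.items()
    }


def one_way_sensitivity(
    schedule: CostSchedule,
    occupancy: Sequence[float],
    parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
    fraction: float = 0.5,
) -> list[SensitivityResult]:
    """Vary each component by +/- ``fraction`` and record the outcome range.

    The outcome is the first-year total cost for the given occupancy
    (undiscounted: year 1 carries no discount/growth factor).
    """
    if not 0.0 <= fraction < 1.0:
        raise DomainError("fraction must lie in [0, 1)")
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (3,) or (occ < 0).any():
        raise DomainError("occupancy must be 3 non-negative values")
    components = _component_vectors(schedule)
    baseline = {name: float(occ @ vec) for name, vec in components.items()}
    base_total = sum(baseline.values())
    results = []
    for name in parameters:
        if name not in components:
            raise ConfigurationError(
                f"unknown sensitivity parameter {name!r}; expected one of "
                f"{sorted(components)}"
            )
        rest = base_total - baseline[name]
        low = rest + (1.0 - fraction) * baseline[name]
        high = rest + (1.0 + fraction) * baseline[name]
        results.append(
            SensitivityResult(
                parameter=name,
                low_value=1.0 - fraction,
                high_value=1.0 + fraction,
                outcome_low=low,
                outcome_high=high,
                range=abs(high - low),
            )
        )
    return results


def tornado_table(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    """Rank results by descending range; ties break alphabetically."""
    if not results:
        raise DomainError("tornado table requires at least one result")
    ordered = sorted(results, key=lambda r: (-r.range, r.parameter))
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in ordered],
            "low": [r.outcome_low for r in ordered],
            "high": [r.outcome_high for r in ordered],
            "range": [r.range for r in ordered],
            "rank": np.arange(1, len(ordered) + 1),
        }
    )


def tornado_plot(results: Sequence[SensitivityResult], path: Optional[str] = None):
    """Horizontal tornado diagram of the outcome ranges (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = tornado_table(results).iloc[::-1]  # widest bar on top
    base = (table["low"] + table["high"]) / 2.0
    fig, ax = plt.subplots(figsize=(7, 0.8 * len(table) + 1.5))
    ax.barh(table["parameter"], table["high"] - table["low"], left=table["low"], color="#4878b0")
    ax.axvline(float(base.iloc[0]), color="k", lw=0.8)
    ax.set_xlabel("first-year total cost (EUR)")
    ax.set_title("One-way sensitivity of first-year total cost")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
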