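"""Synthetic longitudinal client registry.

The clinical registry behind the cost model (an Austrian dementia-service
database) is not publicly deposited, so this module generates datasets with
the statistical structure the analysis assumes: a baseline severity mix,
annual transitions driven by a row-stochastic 3x3 matrix, missing-at-random
follow-up dropout, and a weak positive rank association between severity
and the ordinal long-term care benefit level.

The generator is deterministic: identical config (including seed) yields a
byte-identical CSV file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParseError
from .ingest import GDS_BY_STATE, STATES, ClientRecord, SeverityState

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "write_registry",
    "read_registry",
    "DEFAULT_TRUE_MATRIX",
]

#: Default annual severity transition matrix for synthetic cohorts.  The
#: real registry's estimated matrix is not public; this stand-in encodes
#: the qualitative progression pattern of outpatient dementia cohorts:
#: strong persistence on the diagonal, mostly-forward movement, a small
#: mild<->moderate back-flow, and essentially no recovery from severe.
DEFAULT_TRUE_MATRIX = np.array(
    [
        [0.78, 0.18, 0.04],
        [0.08, 0.68, 0.24],
        [0.01, 0.05, 0.94],
    ]
)

#: Baseline mix of the paired analysis cohort (mild, moderate, severe),
#: normalized from the 784/413/144 head counts the model is run on.
DEFAULT_BASELINE_MIX = (784.0, 413.0, 144.0)

#: Registry size and dropout chosen so that ~4817 baseline clients yield
#: ~1341 usable follow-up pairs, matching the selection flow the model
#: assumes.
DEFAULT_N_CLIENTS = 4817
DEFAULT_DROPOUT = 1.0 - 1341.0 / 4817.0

CSV_COLUMNS = ["client_id", "gds_baseline", "gds_followup", "benefit_level", "age", "sex"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic registry.

    Parameters
    ----------
    n_clients
        Number of baseline clients to generate.
    baseline_mix
        Non-negative weights (mild, moderate, severe); normalized internally.
    true_matrix
        Row-stochastic 3x3 annual transition matrix.
    dropout_prob
        Probability that the follow-up observation is missing
        (missing-completely-at-random by default).
    dropout_severity_multiplier
        Optional informative-dropout knob: the dropout odds for moderate and
        severe clients are multiplied by this factor (and its square,
        respectively).  1.0 keeps dropout MCAR.
    benefit_correlation
        Loading of the latent benefit variable on severity; the default
        0.21 yields a Spearman rank correlation of roughly 0.2 between
        severity state and benefit level, the weak association seen in
        comparable registries.
    seed
        PRNG seed; a single stream drives the whole generation.
    """

    n_clients: int = DEFAULT_N_CLIENTS
    baseline_mix: Sequence[float] = DEFAULT_BASELINE_MIX
    true_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_MATRIX.copy())
    dropout_prob: float = DEFAULT_DROPOUT
    dropout_severity_multiplier: float = 1.0
    benefit_correlation: float = 0.21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients <= 0:
            raise ConfigurationError("n_clients must be positive")
        mix = np.asarray(self.baseline_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or mix.sum() <= 0:
            raise ConfigurationError("baseline_mix must be 3 non-negative weights")
        matrix = np.asarray(self.true_matrix, dtype=float)
        if matrix.shape != (3, 3) or (matrix < 0).any():
            raise ConfigurationError("true_matrix must be a non-negative 3x3 matrix")
        for i, row_sum in enumerate(matrix.sum(axis=1)):
            if abs(row_sum - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"true_matrix row {i} sums to {row_sum!r}, expected 1"
                )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")
        object.__setattr__(self, "baseline_mix", tuple(mix / mix.sum()))
        object.__setattr__(self, "true_matrix", matrix)


def _gds_within(state: SeverityState, rng: np.random.Generator) -> int:
    """Pick a concrete GDS level uniformly within a severity state."""
    levels = GDS_BY_STATE[state]
    return int(levels[rng.integers(len(levels))]) if len(levels) > 1 else levels[0]


# Equal-mass standard-normal cut points for the 7 ordinal benefit tiers.
_BENEFIT_CUTS = stats.norm.ppf(np.arange(1, 7) / 7.0)


def generate_cohort(config: GeneratorConfig) -> list[ClientRecord]:
    """Generate a synthetic cohort of :class:`ClientRecord`.

    Baseline severity states are drawn from ``baseline_mix``; each
    non-dropout client's follow-up state is drawn from the ``true_matrix``
    row of its baseline state.  GDS values are uniform within the state's
    levels.  Benefit level is an ordinal 1-7 obtained by discretizing a
    latent Gaussian correlated with severity.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clients
    mix = np.asarray(config.baseline_mix)
    matrix = config.true_matrix

    baseline_states = rng.choice(3, size=n, p=mix)

    # Follow-up: one categorical draw per client from its baseline row.
    u = rng.random(n)
    cum = matrix.cumsum(axis=1)
    followup_states = (u[:, None] > cum[baseline_states]).sum(axis=1)

    # Dropout: MCAR by default, optionally odds-scaled by severity.
    p_drop = np.full(n, config.dropout_prob)
    if config.dropout_severity_multiplier != 1.0 and 0.0 < config.dropout_prob < 1.0:
        odds = config.dropout_prob / (1.0 - config.dropout_prob)
        mult = config.dropout_severity_multiplier ** baseline_states.astype(float)
        scaled = odds * mult
        p_drop = scaled / (1.0 + scaled)
    dropped = rng.random(n) < p_drop

    # Benefit level: latent = c * severity_z + sqrt(1-c^2) * noise, binned
    # into 7 equal-mass ordinal tiers.
    c = float(np.clip(config.benefit_correlation, -1.0, 1.0))
    sev = baseline_states.astype(float)
    sev_sd = sev.std()
    sev_z = (sev - sev.mean()) / sev_sd if sev_sd > 0 else np.zeros(n)
    latent = c * sev_z + np.sqrt(1.0 - c * c) * rng.standard_normal(n)
    benefit = np.digitize(latent, _BENEFIT_CUTS) + 1  # 1..7

    ages = np.round(rng.normal(77.9, 9.7, size=n), 1)
    sexes = np.where(rng.random(n) < 0.659, "F", "M")

    records = []
    width = len(str(n))
    for k in range(n):
        b_state = SeverityState(int(baseline_states[k]))
        gds_b = _gds_within(b_state, rng)
        if dropped[k]:
            gds_f: Optional[int] = None
        else:
            f_state = SeverityState(int(followup_states[k]))
            gds_f = _gds_within(f_state, rng)
        records.append(
            ClientRecord(
                client_id=f"C{k + 1:0{width}d}",
                gds_baseline=gds_b,
                gds_followup=gds_f,
                benefit_level=int(benefit[k]),
                age=float(ages[k]),
                sex=str(sexes[k]),
            )
        )
    return records


def write_registry(records: Sequence[ClientRecord], path: Union[str, Path]) -> None:
    """Write records to a UTF-8 CSV with the registry schema.

    Missing follow-up / benefit / age / sex are encoded as empty fields.
    An empty collection produces a header-only file.
    """
    frame = pd.DataFrame(
        [
            {
                "client_id": r.client_id,
                "gds_baseline": r.gds_baseline,
                "gds_followup": "" if r.gds_followup is None else r.gds_followup,
                "benefit_level": "" if r.benefit_level is None else r.benefit_level,
                "age": "" if r.age is None else r.age,
                "sex": "" if r.sex is None else r.sex,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def _parse_optional_int(raw: str, row: int, column: str, lo: int, hi: int) -> Optional[int]:
    if raw == "":
        return None
    try:
        value = int(raw)
    except ValueError:
        raise ParseError(f"row {row}: {column}={raw!r} is not an integer") from None
    if not lo <= value <= hi:
        raise ParseError(f"row {row}: {column}={value} outside {lo}..{hi}")
    return value


def read_registry(path: Union[str, Path]) -> list[ClientRecord]:
    """Read a registry CSV back into records.

    Raises
    ------
    ParseError
        On a malformed row (non-integer or out-of-range GDS / benefit),
        naming the offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"registry is missing columns: {missing}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        gds_b = _parse_optional_int(row.gds_baseline, idx, "gds_baseline", 1, 7)
        if gds_b is None:
            raise ParseError(f"row {idx}: gds_baseline is missing")
        gds_f = _parse_optional_int(row.gds_followup, idx, "gds_followup", 1, 7)
        benefit = _parse_optional_int(row.benefit_level, idx, "benefit_level", 1, 7)
        age = None if row.age == "" else float(row.age)
        sex = None if row.sex == "" else row.sex
        records.append(
            ClientRecord(
                client_id=row.client_id,
                gds_baseline=gds_b,
                gds_followup=gds_f,
                benefit_level=benefit,
                age=age,
                sex=sex,
            )
        )
    return records
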