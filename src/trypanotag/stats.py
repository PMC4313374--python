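"""Transfection statistics: zero-class Poisson correction of 96-well counts.

After plating a whole transfection across N wells, the number of wells with
visible growth m underestimates the number of transfectants n because wells
can receive more than one clone. Assuming transfectants distribute randomly
and independently among wells (well occupancy ~ Poisson with mean n/N), the
fraction of empty wells estimates exp(-n/N), giving

    n = -N * ln(1 - m/N)

m = N carries no information (no empty wells; the estimate is unbounded)
and raises SaturationError. The optional 95% interval inverts the binomial
distribution of empty wells (Clopper-Pearson on the empty-well fraction,
mapped through the same log transform). Per-cell efficiency is n divided by
the number of cells transfected (e.g. 1.2e7 in a standard nucleofection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import SaturationError, UsageError


@dataclass
class WellCountEstimate:
    n_wells: int
    m_positive: int
    n_transfectants: float
    efficiency: float | None = None  # transfectants per cell
    ci95: tuple[float, float] | None = None


def estimate_transfectants(
    n_wells: int,
    m_positive: int,
    cells_transfected: float | None = None,
    ci: bool = True,
) -> WellCountEstimate:
    """Zero-class Poisson estimate of the transfectant count from well counts."""
    N, m = n_wells, m_positive
    if N <= 0 or m < 0 or m > N:
        raise UsageError(f"need 0 <= positive wells <= total wells, got m={m}, N={N}")
    if m == N:
        raise SaturationError(
            f"all {N} wells positive: zero empty wells carry no information "
            "(dilute further and re-plate)"
        )
    n_est = 0.0 if m == 0 else -N * float(np.log(1.0 - m / N))

    interval = None
    if ci:
        # Clopper-Pearson bounds on the per-well occupancy probability m/N,
        # mapped through n = -N ln(1 - p)
        alpha = 0.05
        p_lo = 0.0 if m == 0 else float(sps.beta.ppf(alpha / 2, m, N - m + 1))
        p_hi = float(sps.beta.ppf(1 - alpha / 2, m + 1, N - m))
        hi = float("inf") if p_hi >= 1.0 else -N * float(np.log(1.0 - p_hi))
        interval = (-N * float(np.log(1.0 - p_lo)), hi)

    eff = None
    if cells_transfected is not None:
        if cells_transfected <= 0:
            raise UsageError("cells_transfected must be positive")
        eff = n_est / cells_transfected
    return WellCountEstimate(N, m, n_est, eff, interval)


def simulate_plating(
    n_transfectants: int,
    n_wells: int,
    replicates: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Distribute transfectants into wells uniformly at random; return the
    number of occupied wells per replicate (the estimator's oracle)."""
    if n_transfectants < 0 or n_wells <= 0 or replicates <= 0:
        raise UsageError("inputs must be non-negative (wells/replicates positive)")
    rng = np.random.default_rng(seed)
    if n_transfectants == 0:
        return np.zeros(replicates, dtype=int)
    wells = rng.integers(0, n_wells, size=(replicates, n_transfectants))
    out = np.empty(replicates, dtype=int)
    for i in range(replicates):
        out[i] = np.unique(wells[i]).size
    return out
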