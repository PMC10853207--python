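"""CENTURY-style first-order multi-pool carbon model (TECO).

A conventional comparison model without explicit microbes: seven pools
(foliage, root, metabolic litter, structural litter, fast / slow / passive
SOM) decompose proportionally to pool size times an environmental scalar
xi(T, theta) = Q10^((T-Tref)/10) * theta^b. Decomposed C is partitioned to
downstream pools by a fixed transfer matrix; the remainder is respired.

Pools are in mg C per g soil (matching the microbial-explicit model so the
two can share forcing); rates are per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mend import Forcing

__all__ = ["TecoParams", "TecoState", "TECO_POOLS", "simulate_teco",
           "TECO_PARAM_NAMES", "DEFAULT_TECO_BOUNDS"]

TECO_POOLS = ("foliage", "root", "litter_metabolic", "litter_structural",
              "som_fast", "som_slow", "som_passive")

#: CENTURY-lineage transfer fractions: entry (i, j) is the share of pool
#: j's decomposition flux entering pool i; column remainders are respired.
DEFAULT_TRANSFER = np.array([
    #  fol   root  met   str   fast  slow  pass
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],   # foliage
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],   # root
    [0.60, 0.45, 0.00, 0.00, 0.00, 0.00, 0.00],   # metabolic litter
    [0.40, 0.55, 0.00, 0.00, 0.00, 0.00, 0.00],   # structural litter
    [0.00, 0.00, 0.45, 0.35, 0.00, 0.42, 0.45],   # fast SOM
    [0.00, 0.00, 0.00, 0.25, 0.30, 0.00, 0.00],   # slow SOM
    [0.00, 0.00, 0.00, 0.00, 0.05, 0.03, 0.00],   # passive SOM
])

TECO_PARAM_NAMES = ("k_foliage", "k_root", "k_litter_metabolic",
                    "k_litter_structural", "k_som_fast", "k_som_slow",
                    "k_som_passive", "q10", "moisture_b", "t_ref")

DEFAULT_TECO_BOUNDS: dict[str, tuple[float, float]] = {
    "k_foliage": (1e-4, 0.05),
    "k_root": (1e-4, 0.02),
    "k_litter_metabolic": (1e-3, 0.2),
    "k_litter_structural": (1e-4, 0.05),
    "k_som_fast": (1e-5, 0.01),
    "k_som_slow": (1e-6, 1e-3),
    "k_som_passive": (1e-8, 1e-5),
    "q10": (1.2, 3.5),
    "moisture_b": (0.1, 2.0),
    "t_ref": (10.0, 30.0),
}


@dataclass
class TecoParams:
    """Baseline turnover rates (1/d) and environmental scaling parameters."""

    k_foliage: float = 0.005
    k_root: float = 0.002
    k_litter_metabolic: float = 0.03
    k_litter_structural: float = 0.005
    k_som_fast: float = 5e-4
    k_som_slow: float = 5e-5
    k_som_passive: float = 1e-6
    q10: float = 2.0
    moisture_b: float = 0.5
    t_ref: float = 20.0
    transfer: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSFER.copy())
    #: GPP allocation to (foliage, root)
    gpp_split: tuple[float, float] = (0.6, 0.4)

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k_foliage, self.k_root,
                         self.k_litter_metabolic, self.k_litter_structural,
                         self.k_som_fast, self.k_som_slow,
                         self.k_som_passive])

    def validate(self) -> None:
        if np.any(self.k <= 0):
            raise ValueError("turnover rates must be positive")
        t = self.transfer
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("transfer fractions outside [0, 1]")
        if np.any(t.sum(axis=0) > 1.0 + 1e-12):
            raise ValueError("transfer column sums exceed 1")

    def with_values(self, **kwargs: float) -> "TecoParams":
        return replace(self, **kwargs)


@dataclass
class TecoState:
    """Seven pool sizes plus cumulative heterotrophic respiration."""

    pools: np.ndarray
    rh_cum: float = 0.0

    @classmethod
    def default(cls) -> "TecoState":
        # prairie-like standing stocks, mg C/g soil
        return cls(np.array([0.5, 1.0, 0.3, 1.2, 4.0, 12.0, 4.0]), 0.0)


def _xi(temp_c: float, theta: float, p: TecoParams) -> float:
    x = p.q10 ** ((temp_c - p.t_ref) / 10.0)
    return x * theta ** p.moisture_b if theta > 0 else 0.0


def simulate_teco(state: TecoState, p: TecoParams, forcing: Forcing,
                  step_d: float = 1.0, duration_d: float | None = None,
                  ) -> dict:
    """Integrate the first-order system with RK4 at a daily step.

    ``forcing`` is shared with the microbial model (hourly units for
    litter input); its ``litter_rate`` feeds the two litter pools directly
    and GPP-derived plant input is represented through the plant pools.
    Returns time (days), pool trajectory, interval Rh and cumulative Rh.
    """
    p.validate()
    if duration_d is None:
        duration_d = forcing.duration / 24.0
    n = int(round(duration_d / step_d))

    tr = p.transfer
    resp_frac = 1.0 - tr.sum(axis=0)
    k = p.k

    def deriv(y: np.ndarray, t_d: float) -> np.ndarray:
        temp, theta, _, lit, _ = forcing.at(t_d * 24.0)
        xi = _xi(temp, theta, p)
        pools = np.maximum(y[:7], 0.0)
        dec = k * pools * xi
        dy = np.empty(8)
        dy[:7] = tr @ dec - dec
        # litter input (mg C/g/h -> per day) into the plant pools
        gpp = lit * 24.0
        dy[0] += gpp * p.gpp_split[0]
        dy[1] += gpp * p.gpp_split[1]
        dy[7] = float(resp_frac @ dec)
        return dy

    y = np.concatenate([state.pools.astype(float), [state.rh_cum]])
    times = np.empty(n + 1)
    traj = np.empty((n + 1, 8))
    times[0], traj[0] = 0.0, y
    t = 0.0
    for i in range(n):
        h = step_d
        k1 = deriv(y, t)
        k2 = deriv(y + 0.5 * h * k1, t + 0.5 * h)
        k3 = deriv(y + 0.5 * h * k2, t + 0.5 * h)
        k4 = deriv(y + h * k3, t + h)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        times[i + 1], traj[i + 1] = t, y

    rh_cum = traj[:, 7]
    return {
        "time_d": times,
        "pools": traj[:, :7],
        "rh_cum": rh_cum,
        "rh": np.diff(rh_cum, prepend=rh_cum[0]),
        "total_c": traj[:, :7].sum(axis=1) + rh_cum,
    }
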