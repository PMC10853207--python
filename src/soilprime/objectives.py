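"""Goodness-of-fit statistics, weighted multi-objective functions and the
F-distribution parameter-uncertainty threshold (COFI).

The calibration machinery minimises a composite objective
J = sum_i w_i * J_i (weights on the simplex), where each J_i maps a
simulated-vs-observed comparison into [0, inf): MARE for sparse absolute
variables, 1 - R^2 for densely observed fluxes, and (1 - r)/2 for series
observed only up to an unknown positive scale (gene-abundance proxies of
enzyme concentration).

Parameter uncertainty is quantified with the Critical Objective Function
Index: J_cr = J_opt * (1 + p/(n-p) * F(alpha; p, n-p)). Every evaluated
parameter vector with J <= J_cr is "feasible"; per-parameter ranges and
coefficients of variation over the feasible set express identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FitStatistics",
    "ObjectiveSpec",
    "goodness_of_fit",
    "mare",
    "r_squared",
    "pearson_r",
    "objective_value",
    "composite_objective",
    "LAB_OBJECTIVE_WEIGHTS",
    "FIELD_OBJECTIVE_WEIGHTS",
    "CofiResult",
    "cofi_feasible",
]

#: laboratory preset: cumulative CO2 dominates (w=5/8)
LAB_OBJECTIVE_WEIGHTS = {"co2": 5 / 8, "enz_o": 1 / 8, "enz_h": 1 / 8,
                         "active_fraction": 1 / 8}
#: field preset: Rh dominates (w=5/9)
FIELD_OBJECTIVE_WEIGHTS = {"rh": 5 / 9, "mbc": 1 / 9,
                           "active_fraction": 1 / 9,
                           "enz_o": 1 / 9, "enz_h": 1 / 9}

STATISTICS = ("MARE", "one_minus_R2", "one_minus_r_over_2")


@dataclass
class FitStatistics:
    """MARE, coefficient of determination and Pearson correlation."""

    mare: float
    r2: float
    r: float


def mare(obs: np.ndarray, sim: np.ndarray) -> float:
    """Mean absolute relative error; observations must be nonzero."""
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    if np.any(obs == 0):
        raise ValueError("MARE undefined for zero observations")
    return float(np.mean(np.abs((sim - obs) / obs)))


def r_squared(obs: np.ndarray, sim: np.ndarray) -> float:
    """1 - SSE/SST; can be negative for fits worse than the mean."""
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observations; R2 undefined")
    return 1.0 - float(np.sum((sim - obs) ** 2)) / sst


def pearson_r(obs: np.ndarray, sim: np.ndarray) -> float:
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    so, ss = obs.std(), sim.std()
    if so == 0 or ss == 0:
        raise ValueError("constant series; correlation undefined")
    return float(np.corrcoef(obs, sim)[0, 1])


def goodness_of_fit(obs: np.ndarray, sim: np.ndarray) -> FitStatistics:
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    if obs.shape != sim.shape or obs.size < 2:
        raise ValueError("series must have equal length >= 2")
    return FitStatistics(
        mare=mare(obs, sim) if np.all(obs != 0) else float("nan"),
        r2=r_squared(obs, sim),
        r=pearson_r(obs, sim))


def objective_value(obs: np.ndarray, sim: np.ndarray, statistic: str) -> float:
    """One J_i component; lower is better, perfect fit gives 0."""
    if statistic == "MARE":
        return mare(obs, sim)
    if statistic == "one_minus_R2":
        return 1.0 - r_squared(obs, sim)
    if statistic == "one_minus_r_over_2":
        return (1.0 - pearson_r(obs, sim)) / 2.0
    raise ValueError(f"unknown statistic {statistic!r}; use one of {STATISTICS}")


@dataclass
class ObjectiveSpec:
    """Weighted list of (variable, statistic) objective components."""

    components: list[tuple[str, str, float]]  # (variable, statistic, weight)

    def __post_init__(self) -> None:
        w = np.array([c[2] for c in self.components], float)
        if np.any((w < 0) | (w > 1)) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must lie in [0,1] and sum to 1")
        for _, stat, _ in self.components:
            if stat not in STATISTICS:
                raise ValueError(f"unknown statistic {stat!r}")

    @classmethod
    def lab(cls) -> "ObjectiveSpec":
        # all lab variables have directly comparable absolute values
        return cls([("co2", "MARE", 5 / 8),
                    ("enz_o", "MARE", 1 / 8),
                    ("enz_h", "MARE", 1 / 8),
                    ("active_fraction", "MARE", 1 / 8)])

    @classmethod
    def lab_co2_only(cls) -> "ObjectiveSpec":
        return cls([("co2", "MARE", 1.0)])

    @classmethod
    def field(cls, variables: tuple[str, ...] = ("rh", "mbc",
                                                 "active_fraction",
                                                 "enz_o", "enz_h"),
              ) -> "ObjectiveSpec":
        """Field preset restricted to ``variables``, Rh re-weighted 5:1."""
        stat = {"rh": "one_minus_R2", "mbc": "MARE",
                "active_fraction": "MARE", "enz_o": "one_minus_r_over_2",
                "enz_h": "one_minus_r_over_2"}
        raw = {v: (5.0 if v == "rh" else 1.0) for v in variables}
        tot = sum(raw.values())
        return cls([(v, stat[v], w / tot) for v, w in raw.items()])

    @property
    def variables(self) -> list[str]:
        return [c[0] for c in self.components]


def composite_objective(values: dict[str, float], spec: ObjectiveSpec,
                        allow_missing: bool = False) -> float:
    """J = sum_i w_i J_i over the spec's components.

    With ``allow_missing`` the weights are renormalised over the
    components present (used when a temporal split leaves a sparse
    variable without enough training points).
    """
    missing = set(spec.variables) - set(values)
    if missing and not allow_missing:
        raise ValueError(f"missing objective components: {sorted(missing)}")
    comps = [(v, w) for v, _, w in spec.components if v in values]
    wtot = sum(w for _, w in comps)
    if wtot == 0:
        raise ValueError("no objective components available")
    return float(sum(w * values[v] for v, w in comps) / wtot)


@dataclass
class CofiResult:
    """Feasible parameter set defined by the F-distribution threshold."""

    j_opt: float
    j_cr: float
    alpha: float
    n_params: int
    n_obs: int
    feasible: pd.DataFrame          # archive rows with J <= J_cr
    ranges: dict[str, tuple[float, float]]
    cv: dict[str, float]

    def range_width(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return hi - lo

    def mean_cv(self) -> float:
        return float(np.mean(list(self.cv.values())))

    def summary(self) -> pd.DataFrame:
        rows = [{"parameter": k,
                 "best": float(self.feasible.loc[
                     self.feasible.J.idxmin(), k]),
                 "feasible_min": self.ranges[k][0],
                 "feasible_max": self.ranges[k][1],
                 "cv": self.cv[k]}
                for k in self.ranges]
        return pd.DataFrame(rows)


def cofi_feasible(archive: pd.DataFrame, n_obs: int, alpha: float = 0.05,
                  param_names: list[str] | None = None,
                  cv_method: str = "sd", j_floor: float = 0.0) -> CofiResult:
    """Compute the COFI threshold and the feasible parameter set.

    ``archive`` must carry one column per calibrated parameter plus a
    column ``J``; ``n_obs`` is the observation count used in calibration.
    ``cv_method='sd'`` uses sample-sd/mean over the feasible set;
    ``'range'`` uses (max-min)/(max+min), a range-based alternative.

    ``j_floor`` is an observational-precision floor on the optimum:
    objective differences below it are beneath the resolution of the
    data, so the threshold uses max(J_opt, j_floor). Without the floor
    the multiplicative threshold degenerates as J_opt -> 0 (an exact
    fit would declare zero parameter uncertainty).
    """
    if archive.empty:
        raise ValueError("empty calibration archive")
    if param_names is None:
        param_names = [c for c in archive.columns if c != "J"]
    p = len(param_names)
    if n_obs <= p:
        raise ValueError("need more observations than parameters for COFI")
    j_opt = float(archive["J"].min())
    f_crit = float(sps.f.ppf(1.0 - alpha, p, n_obs - p))
    j_cr = max(j_opt, j_floor) * (1.0 + p / (n_obs - p) * f_crit)
    feasible = archive[archive["J"] <= j_cr]
    ranges, cv = {}, {}
    for name in param_names:
        vals = feasible[name].to_numpy(float)
        ranges[name] = (float(vals.min()), float(vals.max()))
        m = float(vals.mean())
        if cv_method == "sd":
            cv[name] = float(vals.std(ddof=1) / abs(m)) if vals.size > 1 and m \
                else 0.0
        elif cv_method == "range":
            lo, hi = ranges[name]
            cv[name] = (hi - lo) / (hi + lo) if hi + lo else 0.0
        else:
            raise ValueError("cv_method must be 'sd' or 'range'")
    return CofiResult(j_opt, j_cr, alpha, p, n_obs, feasible, ranges, cv)
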