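"""Multi-objective calibration of the soil-carbon models.

statsmodels-style surface: a model object is built from an observation set
plus an experimental setup, and ``fit()`` runs a seeded archiving global
optimizer (differential evolution) over the parameter bounds, returning a
:class:`CalibrationResult` that carries the best-fit vector, the full
evaluation archive, goodness-of-fit statistics and the F-distribution
(COFI) feasible ranges / coefficients of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.optimize import minimize as sp_minimize
from scipy.stats import f as sps_f

from .mend import (DEFAULT_BOUNDS, FIELD_PARAM_NAMES, LAB_PARAM_NAMES,
                   Forcing, MendParams, MendState, add_litter,
                   constant_forcing, default_lab_state, simulate_mend)
from .objectives import (CofiResult, ObjectiveSpec, cofi_feasible,
                         composite_objective, goodness_of_fit,
                         objective_value)
from .teco import (DEFAULT_TECO_BOUNDS, TECO_PARAM_NAMES, TecoParams,
                   TecoState, simulate_teco)

logger = logging.getLogger(__name__)

__all__ = [
    "LabSetup", "FieldSetup", "lab_observables", "field_observables",
    "LabMendModel", "FieldMendModel", "TecoModel",
    "CalibrationResult", "calibrate", "sensitivity_ranking",
]

PENALTY_J = 1e6


# ---------------------------------------------------------------------------
# forward maps: experimental setup -> simulated observables
# ---------------------------------------------------------------------------

@dataclass
class LabSetup:
    """Design of the 7-day dual-isotope incubation.

    Both in-situ-warmed and control soils are incubated together; the
    warming legacy is emulated by a temperature offset on the response
    functions and a multiplier on the initial active biomass and enzyme
    stocks of warmed-soil runs.
    """

    days: int = 7
    temp_c: float = 25.0
    warm_offset_c: float = 3.0
    warm_boost: float = 1.4
    straw_mg_c: float = 10.0
    straw_atom13: float = 0.751
    background_atom13: float = 0.0108
    litter_split: tuple[float, float, float] = (0.15, 0.75, 0.10)
    step_h: float = 2.0

    def initial_state(self, warmed: bool) -> MendState:
        return default_lab_state(atom13=self.background_atom13, warmed=warmed)


def lab_case_trajectory(p: MendParams, setup: LabSetup, warmed: bool,
                        straw: str, atom13_override: float | None = None,
                        ) -> dict:
    """Simulate one incubation case; ``straw`` in {'none','c12','c13'}."""
    state = setup.initial_state(warmed)
    if straw != "none":
        a13 = (setup.straw_atom13 if straw == "c13"
               else setup.background_atom13)
        if atom13_override is not None:
            a13 = atom13_override
        state = add_litter(state, setup.straw_mg_c, a13, setup.litter_split)
    temp = setup.temp_c + (setup.warm_offset_c if warmed else 0.0)
    forcing = constant_forcing(setup.days * 24.0, temp_c=temp, params=p)
    return simulate_mend(state, p, forcing, step_h=setup.step_h,
                         duration_h=setup.days * 24.0, output_every_h=24.0)


def lab_observables(p: MendParams, setup: LabSetup) -> dict[str, np.ndarray]:
    """Noise-free observables of the incubation, in model units (mg C/g).

    ``co2``: per treatment, daily cumulative CO2 without straw (d days),
    with 13C straw (d days) and labeled CO2 with 13C straw (d days) —
    42 points for the default 7-day, two-treatment design. ``enz_o``,
    ``enz_h``, ``active_fraction``: end-of-incubation values in the
    13C-straw runs, one per treatment (6 more points).
    """
    co2_parts, enz_o, enz_h, act = [], [], [], []
    for warmed in (False, True):
        none = lab_case_trajectory(p, setup, warmed, "none")
        c13 = lab_case_trajectory(p, setup, warmed, "c13")
        co2_parts += [none["co2_cum"][1:], c13["co2_cum"][1:],
                      c13["co2_cum_labeled"][1:]]
        enz_o.append(c13["enz_o"][-1])
        enz_h.append(c13["enz_h"][-1])
        act.append(c13["active_fraction"][-1])
    return {"co2": np.concatenate(co2_parts), "enz_o": np.array(enz_o),
            "enz_h": np.array(enz_h), "active_fraction": np.array(act)}


@dataclass
class FieldSetup:
    """Multi-year field run: daily forcing, continuous litter input.

    Sparse variables (microbial biomass, active fraction, enzyme-proxy
    gene abundances) are observed every ``sparse_every_d`` days; Rh daily.
    Gene abundances equal enzyme concentration times an unknown positive
    scale, which is why their objective is correlation-based.
    """

    forcing: Forcing
    initial: MendState
    step_h: float = 6.0
    sparse_every_d: int = 30

    @property
    def n_days(self) -> int:
        return int(round(self.forcing.duration / 24.0))

    def sparse_days(self) -> np.ndarray:
        return np.arange(self.sparse_every_d, self.n_days + 1,
                         self.sparse_every_d)


def field_observables(p: MendParams, setup: FieldSetup) -> dict[str, np.ndarray]:
    out = simulate_mend(setup.initial, p, setup.forcing, step_h=setup.step_h,
                        duration_h=setup.n_days * 24.0, output_every_h=24.0)
    sp = setup.sparse_days()
    return {
        "rh": np.diff(out["co2_cum"]),          # daily efflux, mg C/g/d
        "mbc": out["mbc"][sp],
        "active_fraction": out["active_fraction"][sp],
        "enz_o": out["enz_o"][sp],
        "enz_h": out["enz_h"][sp],
    }


def teco_observables(p: TecoParams, setup: FieldSetup,
                     initial: TecoState | None = None) -> dict[str, np.ndarray]:
    out = simulate_teco(initial or TecoState.default(), p, setup.forcing,
                        step_d=1.0, duration_d=setup.n_days)
    return {"rh": np.diff(out["rh_cum"])}


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Archive-backed calibration outcome.

    ``archive`` has one row per objective evaluation with the parameter
    values, each component objective ``J_<variable>`` and the composite
    ``J``. ``params`` is the best-fit parameter dict.
    """

    model: object
    archive: pd.DataFrame
    param_names: list[str]
    spec: ObjectiveSpec
    n_obs: int
    seed: int
    budget: int

    @property
    def j_opt(self) -> float:
        return float(self.archive["J"].min())

    @property
    def params(self) -> dict[str, float]:
        row = self.archive.loc[self.archive["J"].idxmin()]
        return {k: float(row[k]) for k in self.param_names}

    def cofi(self, alpha: float = 0.05, n_obs: int | None = None,
             cv_method: str = "sd") -> CofiResult:
        floor = getattr(self.model, "objective_floor", 0.0)
        return cofi_feasible(self.archive[self.param_names + ["J"]],
                             n_obs or self.n_obs, alpha=alpha,
                             param_names=self.param_names,
                             cv_method=cv_method, j_floor=floor)

    def fit_statistics(self) -> dict[str, object]:
        sim = self.model.observables(self.params)
        return {v: goodness_of_fit(self.model.observations[v], sim[v])
                for v in self.spec.variables}

    def summary(self) -> pd.DataFrame:
        cofi = self.cofi()
        tab = cofi.summary()
        tab.insert(1, "best", tab.pop("best"))
        comp = self.archive.loc[self.archive["J"].idxmin()]
        logger.info("J_opt=%.4g J_cr=%.4g feasible=%d/%d", cofi.j_opt,
                    cofi.j_cr, len(cofi.feasible), len(self.archive))
        tab.attrs["J_opt"] = cofi.j_opt
        tab.attrs["J_cr"] = cofi.j_cr
        tab.attrs["components"] = {
            v: float(comp[f"J_{v}"]) for v in self.spec.variables}
        return tab


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------

class _CalibratableModel:
    """Shared fit() machinery: bounds, observables, objective evaluation."""

    observations: dict[str, np.ndarray]
    spec: ObjectiveSpec
    bounds: dict[str, tuple[float, float]]
    n_obs: int
    #: observational-precision floor on the composite objective: J
    #: differences below this are beneath the data's resolution
    #: (~three significant figures on the observed quantities)
    objective_floor: float = 1e-3

    def observables(self, params: dict[str, float]) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def objective_components(self, params: dict[str, float]) -> dict[str, float]:
        sim = self.observables(params)
        return {v: objective_value(self.observations[v], sim[v], stat)
                for v, stat, _ in self.spec.components}

    def objective(self, params: dict[str, float]) -> float:
        return composite_objective(self.objective_components(params),
                                   self.spec, allow_missing=True)

    def fit(self, budget: int = 2000, seed: int = 0,
            refine_fraction: float = 0.3) -> CalibrationResult:
        """Calibrate within ``budget`` objective evaluations.

        A fraction of the budget is spent after the global search on
        refinement sampling around the optimum, which densifies the
        archive inside the COFI feasible region (the global optimizer
        alone leaves it too sparse for meaningful parameter ranges).
        """
        n_refine = int(budget * refine_fraction)
        res = calibrate(self, self.spec, self.bounds,
                        budget=budget - n_refine, seed=seed,
                        n_obs=self.n_obs)
        if n_refine > 0:
            res = refine_feasible(self, res, n_total=n_refine,
                                  seed=seed + 10_000)
        return res


class LabMendModel(_CalibratableModel):
    """Laboratory incubation data assimilation (5 microbial parameters).

    ``observations`` must hold the keys produced by
    :func:`lab_observables`; ``n_obs`` defaults to 48 (42 respiration
    points from the four incubation cases plus 6 microbial points).
    """

    def __init__(self, observations: dict[str, np.ndarray],
                 setup: LabSetup | None = None,
                 spec: ObjectiveSpec | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 base_params: MendParams | None = None,
                 param_names: tuple[str, ...] = LAB_PARAM_NAMES,
                 n_obs: int = 48):
        self.observations = observations
        self.setup = setup or LabSetup()
        self.spec = spec or ObjectiveSpec.lab()
        self.param_names = list(param_names)
        self.bounds = bounds or {k: DEFAULT_BOUNDS[k] for k in param_names}
        self.base_params = base_params or MendParams()
        self.n_obs = n_obs

    def observables(self, params: dict[str, float]) -> dict[str, np.ndarray]:
        return lab_observables(self.base_params.with_values(**params),
                               self.setup)


class FieldMendModel(_CalibratableModel):
    """Field data assimilation of the microbial-explicit model.

    ``variables`` selects which observation streams enter the objective
    (the five model experiments differ only in this choice and in the
    prior ``bounds``); ``train_mask`` restricts the Rh objective to a
    temporal subset (used by the train/test complexity sweep).
    """

    def __init__(self, observations: dict[str, np.ndarray],
                 setup: FieldSetup,
                 variables: tuple[str, ...] = ("rh", "mbc",
                                               "active_fraction",
                                               "enz_o", "enz_h"),
                 bounds: dict[str, tuple[float, float]] | None = None,
                 base_params: MendParams | None = None,
                 param_names: tuple[str, ...] = FIELD_PARAM_NAMES,
                 train_mask: np.ndarray | None = None,
                 n_obs: int | None = None):
        self.setup = setup
        self.variables = variables
        self.spec = ObjectiveSpec.field(variables)
        self.param_names = list(param_names)
        self.bounds = bounds or {k: DEFAULT_BOUNDS[k] for k in param_names}
        self.base_params = base_params or MendParams()
        self.train_mask = train_mask
        self.observations = {v: observations[v] for v in variables}
        if n_obs is None:
            n_obs = sum(len(np.atleast_1d(self.observations[v]))
                        for v in variables)
        self.n_obs = n_obs

    def observables(self, params: dict[str, float]) -> dict[str, np.ndarray]:
        sim = field_observables(self.base_params.with_values(**params),
                                self.setup)
        return {v: sim[v] for v in self.variables}

    def objective_components(self, params: dict[str, float]) -> dict[str, float]:
        sim = self.observables(params)
        out = {}
        sparse_mask = None
        if self.train_mask is not None:
            # cut sparse series at the same calendar day as the Rh mask
            cutoff_day = int(self.train_mask.sum())
            sparse_mask = self.setup.sparse_days() <= cutoff_day
        for v, stat, _ in self.spec.components:
            obs_v, sim_v = self.observations[v], sim[v]
            if self.train_mask is not None:
                m = self.train_mask if v == "rh" else sparse_mask
                if v != "rh" and m.sum() < 2:
                    continue  # too few points in the training window
                obs_v, sim_v = obs_v[m], sim_v[m]
            out[v] = objective_value(obs_v, sim_v, stat)
        return out


class TecoModel(_CalibratableModel):
    """First-order comparison model calibrated against Rh only."""

    def __init__(self, observations: dict[str, np.ndarray],
                 setup: FieldSetup,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 base_params: TecoParams | None = None,
                 initial: TecoState | None = None,
                 train_mask: np.ndarray | None = None,
                 n_obs: int | None = None):
        self.setup = setup
        self.spec = ObjectiveSpec([("rh", "one_minus_R2", 1.0)])
        self.param_names = list(TECO_PARAM_NAMES)
        self.bounds = bounds or dict(DEFAULT_TECO_BOUNDS)
        self.base_params = base_params or TecoParams()
        self.initial = initial or TecoState.default()
        self.train_mask = train_mask
        self.observations = {"rh": observations["rh"]}
        self.n_obs = n_obs or len(observations["rh"])

    def observables(self, params: dict[str, float]) -> dict[str, np.ndarray]:
        return teco_observables(self.base_params.with_values(**params),
                                self.setup, self.initial)

    def objective_components(self, params: dict[str, float]) -> dict[str, float]:
        sim = self.observables(params)["rh"]
        obs = self.observations["rh"]
        if self.train_mask is not None:
            obs, sim = obs[self.train_mask], sim[self.train_mask]
        return {"rh": objective_value(obs, sim, "one_minus_R2")}


# ---------------------------------------------------------------------------
# optimizer driver
# ---------------------------------------------------------------------------

def calibrate(model: _CalibratableModel, spec: ObjectiveSpec,
              bounds: dict[str, tuple[float, float]], budget: int = 2000,
              seed: int = 0, n_obs: int | None = None) -> CalibrationResult:
    """Differential-evolution calibration with full-archive logging.

    Every objective evaluation (including the initial population) is
    archived; failed simulations receive a penalty J and the search
    continues. Deterministic for a fixed seed and budget.
    """
    names = list(bounds)
    lo_hi = [bounds[k] for k in names]
    for k, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"invalid bounds for {k}: {(lo, hi)}")
    rows: list[dict] = []

    def f(x: np.ndarray) -> float:
        params = dict(zip(names, x.tolist()))
        rec = dict(params)
        try:
            comp = model.objective_components(params)
            j = composite_objective(comp, spec, allow_missing=True)
            if not np.isfinite(j):
                raise FloatingPointError("non-finite objective")
        except Exception as exc:  # noqa: BLE001 - penalise and continue
            logger.debug("evaluation failed at %s: %s", params, exc)
            comp = {v: float("nan") for v in spec.variables}
            j = PENALTY_J
        for v in spec.variables:
            rec[f"J_{v}"] = comp.get(v, float("nan"))
        rec["J"] = j
        rows.append(rec)
        return j

    de_budget = min(int(0.3 * budget), 600)
    popsize = max(6, min(10, de_budget // (8 * len(names))))
    maxiter = max(1, de_budget // (popsize * len(names)) - 1)
    differential_evolution(f, lo_hi, seed=seed, popsize=popsize,
                           maxiter=maxiter, tol=0.0, polish=False,
                           mutation=(0.4, 0.9), recombination=0.9,
                           init="latinhypercube", updating="immediate")
    # archived derivative-free polish. The near-optimal surface is a flat
    # compensated valley, often with deceptive secondary basins, where
    # the population search stalls; simplex descents from several
    # well-separated good points find the basin floor, and the start
    # diversity guards against polishing only a secondary basin.
    nm_budget = budget - len(rows)
    if nm_budget >= 30 * len(names):
        lo = np.array([b[0] for b in lo_hi])
        hi = np.array([b[1] for b in lo_hi])
        fc = lambda x: f(np.clip(x, lo, hi))  # noqa: E731
        # the near-optimal surface is a long, flat compensation valley
        # (e.g. maintenance ratio vs growth yield) on which direct
        # descent stalls at an arbitrary point. Treat it the way sloppy
        # kinetic models are profiled: identify the valley's dominant
        # parameter from the low-J archive cloud, pin it on a grid
        # spanning its bounds, solve the well-conditioned subproblem at
        # each pin by continuation from the neighbouring solution, and
        # finish with full-space simplex restarts from the winner.
        p = len(names)
        for x0 in _diverse_starts(pd.DataFrame(rows), names, lo, hi, k=3):
            minimize(fc, x0, method="Nelder-Mead",
                     options={"maxfev": 120, "xatol": 1e-12,
                              "fatol": 1e-14})
        floor = getattr(model, "objective_floor", 0.0)
        n_grid = 7
        prof_fev = max(80, int(0.14 * nm_budget) // n_grid)
        for _pass in range(2):
            best_h = min(rows, key=lambda r: r["J"])
            x_h = np.array([best_h[k] for k in names])
            comp_order = _sloppy_order(fc, x_h, lo, hi)
            i_s = int(comp_order[0])
            # re-optimise everything except the stiffest parameter when
            # the pin moves: a poorly-converged search archive can
            # misidentify the valley axes, so the subproblem keeps all
            # plausibly sloppy directions free
            sub_dims = ([int(i) for i in comp_order[1:-1]]
                        or [int(comp_order[-1])])

            width = hi[i_s] - lo[i_s]
            grid = np.linspace(lo[i_s] + 0.05 * width,
                               hi[i_s] - 0.05 * width, n_grid)
            best_now = min(rows, key=lambda r: r["J"])
            x_now = np.array([best_now[k] for k in names])

            lo_s, hi_s = lo[sub_dims], hi[sub_dims]
            warm = {"u": (x_now[sub_dims] - lo_s) / (hi_s - lo_s)}

            def profile(g: float, fev: int) -> float:
                # normalised coordinates with an explicit wide simplex:
                # the default simplex scales with the start value and
                # cannot traverse the valley from a small-valued start
                def fsub(u: np.ndarray) -> float:
                    x = x_now.copy()
                    x[sub_dims] = lo_s + np.clip(u, 0, 1) * (hi_s - lo_s)
                    x[i_s] = g
                    return fc(x)

                u0 = warm["u"]
                simplex = np.vstack([u0] + [u0 + 0.15 * e
                                            for e in np.eye(len(sub_dims))])
                r_sub = minimize(fsub, u0, method="Nelder-Mead",
                                 options={"maxfev": fev, "xatol": 1e-12,
                                          "fatol": 1e-14,
                                          "initial_simplex": simplex})
                warm["u"] = np.clip(r_sub.x, 0, 1)
                return float(r_sub.fun)

            # coarse sweep outward from the incumbent's pin value
            order = np.argsort(np.abs(grid - x_now[i_s]))
            prof_j = {}
            for gi in order:
                if budget - len(rows) <= 0:
                    break
                prof_j[gi] = profile(grid[gi], prof_fev)
            if not prof_j:
                break
            gi_best = min(prof_j, key=prof_j.get)

            # golden-section refinement of the pin in the winning cell
            a = grid[max(gi_best - 1, 0)]
            b = grid[min(gi_best + 1, n_grid - 1)]
            inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
            c, d = b - inv_phi * (b - a), a + inv_phi * (b - a)
            jc = profile(c, prof_fev)
            jd = profile(d, prof_fev)
            # bisect while the pin still moves materially, reserving
            # budget for the polish (and a second pass if needed)
            golden_reserve = 400 if _pass else 400 + 6 * prof_fev
            while (budget - len(rows) >= prof_fev + golden_reserve
                   and (b - a) > 0.005 * width):
                if jc < jd:
                    b, d, jd = d, c, jc
                    c = b - inv_phi * (b - a)
                    jc = profile(c, prof_fev)
                else:
                    a, c, jc = c, d, jd
                    d = a + inv_phi * (b - a)
                    jd = profile(d, prof_fev)
            # full-space polish from the incumbent
            remaining = budget - len(rows)
            polish = remaining if _pass else min(300, remaining)
            if polish >= 10 * p:
                best_now = min(rows, key=lambda r: r["J"])
                x0 = np.array([best_now[k] for k in names])
                minimize(fc, x0, method="Nelder-Mead",
                         options={"maxfev": polish, "xatol": 1e-12,
                                  "fatol": 1e-14})
            # a second pass only pays when the optimum is still above
            # the data-precision floor and budget remains
            if (min(r["J"] for r in rows) <= max(floor, 1e-12)
                    or budget - len(rows) < n_grid * prof_fev + 200):
                break
    archive = pd.DataFrame(rows)
    return CalibrationResult(model=model, archive=archive, param_names=names,
                             spec=spec, n_obs=n_obs or getattr(model, "n_obs"),
                             seed=seed, budget=budget)


def _sloppy_order(feval, x0: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray, h: float = 0.01) -> list[int]:
    """Order parameters by their weight in the objective's sloppiest
    Hessian eigendirection at ``x0`` (finite differences in normalised
    coordinates). Unlike a PCA of sampled points, this is unaffected by
    how the archive happens to have been sampled.
    """
    p = len(x0)
    u0 = (x0 - lo) / (hi - lo)

    def fu(u: np.ndarray) -> float:
        return feval(lo + np.clip(u, 0.0, 1.0) * (hi - lo))

    j0 = fu(u0)
    hess = np.empty((p, p))
    for i in range(p):
        e = np.eye(p)[i] * h
        hess[i, i] = (fu(u0 + e) + fu(u0 - e) - 2.0 * j0) / h ** 2
    for i in range(p):
        for k in range(i + 1, p):
            e = (np.eye(p)[i] + np.eye(p)[k]) * h
            cross = (fu(u0 + e) + fu(u0 - e) - 2.0 * j0) / h ** 2
            hess[i, k] = hess[k, i] = 0.5 * (cross - hess[i, i]
                                             - hess[k, k])
    evl, vecs = np.linalg.eigh(hess)
    v = np.abs(vecs[:, 0])  # smallest curvature = valley direction
    return [int(i) for i in np.argsort(v)[::-1]]


def _diverse_starts(archive: pd.DataFrame, names: list[str],
                    lo: np.ndarray, hi: np.ndarray, k: int = 4,
                    top_frac: float = 0.25) -> list[np.ndarray]:
    """Greedy max-min selection of well-separated good archive points."""
    top = archive.nsmallest(max(k, int(top_frac * len(archive))), "J")
    pts = top[names].to_numpy(float)
    unit = (pts - lo) / (hi - lo)
    chosen = [0]  # best point first (archive sorted by J)
    while len(chosen) < min(k, len(pts)):
        d = np.min(
            [np.linalg.norm(unit - unit[c], axis=1) for c in chosen],
            axis=0)
        d[chosen] = -1.0
        chosen.append(int(np.argmax(d)))
    return [pts[c] for c in chosen]


def refine_feasible(model: _CalibratableModel, result: CalibrationResult,
                    n_total: int = 600, batch: int = 25, seed: int = 0,
                    alpha: float = 0.05) -> CalibrationResult:
    """Densify the archive inside the COFI feasible region.

    The global search leaves few evaluations below the COFI threshold,
    so feasible parameter ranges computed from the raw archive alone are
    spuriously narrow. This stage samples around the best-fit vector
    with a per-dimension Gaussian step that adapts to the feasible
    acceptance rate (shrinking when almost nothing lands under J_cr,
    growing when most samples do), and, once the feasible cloud is
    populated, also along the cloud's own covariance — which follows the
    curved near-optimal valley typical of compensated parameters. All
    evaluations use the true objective and are appended to the archive.
    """
    names = result.param_names
    p = len(names)
    lo_b = np.array([model.bounds[k][0] for k in names])
    hi_b = np.array([model.bounds[k][1] for k in names])
    f_crit = float(sps_f.ppf(1.0 - alpha, p, result.n_obs - p))
    cof = 1.0 + p / (result.n_obs - p) * f_crit
    floor = getattr(model, "objective_floor", 0.0)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    archive = result.archive
    j_opt_entry = float(archive["J"].min())
    sd = 0.005 * (hi_b - lo_b)

    def evaluate(x: np.ndarray) -> dict:
        params = dict(zip(names, x.tolist()))
        rec = dict(params)
        try:
            comp = model.objective_components(params)
            j = composite_objective(comp, result.spec, allow_missing=True)
            if not np.isfinite(j):
                raise FloatingPointError
        except Exception:  # noqa: BLE001
            comp, j = {}, PENALTY_J
        for v in result.spec.variables:
            rec[f"J_{v}"] = comp.get(v, float("nan"))
        rec["J"] = j
        return rec

    # --- boundary tracing: walk outward from the best vector to the
    # J_cr crossing along each parameter axis and along the principal
    # axes of the low-J archive cloud (which follow the curved
    # compensation valley typical of microbial kinetic parameters).
    # This resolves per-parameter feasible extents at any depth of
    # convergence — the feasible set can be arbitrarily small around a
    # deeply polished optimum, where blind sampling cannot see it.
    def trace_boundaries(arch: pd.DataFrame) -> pd.DataFrame:
        j_cr0 = max(float(arch["J"].min()), floor) * cof
        best0 = arch.loc[arch["J"].idxmin(), names].to_numpy(float)
        traced: list[dict] = []

        def prof_eval(x: np.ndarray) -> float:
            rec = evaluate(np.clip(x, lo_b, hi_b))
            traced.append(rec)
            return rec["J"]

        directions = [np.eye(p)[i] for i in range(p)]
        for d in directions:
            d = d / np.linalg.norm(d / (hi_b - lo_b))
            for sign in (-1.0, 1.0):
                def j_at(t: float) -> float:
                    return prof_eval(best0 + sign * t * d)

                with np.errstate(divide="ignore", invalid="ignore"):
                    lim = np.where(
                        sign * d > 0, (hi_b - best0) / (sign * d),
                        np.where(sign * d < 0,
                                 (lo_b - best0) / (sign * d), np.inf))
                t_max = float(np.min(lim[np.isfinite(lim)]))
                if t_max <= 0:
                    continue
                if j_at(t_max) <= j_cr0:
                    continue  # feasible all the way to the bound
                t = t_max
                while t > 1e-14 * t_max:
                    t /= 2.0
                    if j_at(t) <= j_cr0:
                        break
                else:
                    continue  # no feasible extent in this direction
                t_lo_, t_hi_ = t, min(2.0 * t, t_max)
                for _ in range(6):
                    mid = 0.5 * (t_lo_ + t_hi_)
                    if j_at(mid) <= j_cr0:
                        t_lo_ = mid
                    else:
                        t_hi_ = mid
        return pd.DataFrame(traced)

    # --- profile walk along the compensation valley: the sloppiest
    # parameter (dominant Hessian eigendirection component) is pinned
    # at increasing offsets from the optimum and the remaining sloppy
    # parameters re-optimised by warm-started continuation; the walk
    # continues while the profiled objective stays feasible. Straight
    # rays cannot follow the curved valley, this can.
    def do_walk(arch: pd.DataFrame) -> pd.DataFrame:
        walk_rows: list[dict] = []
        if len(arch) < p + 2:
            return pd.DataFrame(walk_rows)
        best_w = arch.loc[arch["J"].idxmin(), names].to_numpy(float)

        def _eval_j(x: np.ndarray) -> float:
            rec = evaluate(x)
            walk_rows.append(rec)
            return rec["J"]

        comp_order = _sloppy_order(_eval_j, best_w, lo_b, hi_b)
        i_s = int(comp_order[0])
        sub_dims = ([int(i) for i in comp_order[1:-1]]
                    or [int(comp_order[-1])])
        j_cr_w = max(float(arch["J"].min()), floor) * cof
        delta = 0.03 * (hi_b[i_s] - lo_b[i_s])
        lo_s, hi_s = lo_b[sub_dims], hi_b[sub_dims]
        for sign in (1.0, -1.0):
            u = (best_w[sub_dims] - lo_s) / (hi_s - lo_s)
            for k in range(1, 8):
                g = np.clip(best_w[i_s] + sign * k * delta,
                            lo_b[i_s], hi_b[i_s])

                def fsub(uu: np.ndarray) -> float:
                    x = best_w.copy()
                    x[sub_dims] = lo_s + np.clip(uu, 0, 1) * (hi_s - lo_s)
                    x[i_s] = g
                    rec = evaluate(x)
                    walk_rows.append(rec)
                    return rec["J"]

                simplex = np.vstack([u] + [u + 0.05 * e
                                           for e in np.eye(len(sub_dims))])
                res_w = sp_minimize(fsub, u, method="Nelder-Mead",
                                    options={"maxfev": 60,
                                             "xatol": 1e-10,
                                             "fatol": 1e-12,
                                             "initial_simplex": simplex})
                u = np.clip(res_w.x, 0, 1)
                if res_w.fun > j_cr_w:
                    break
        return pd.DataFrame(walk_rows)

    def gaussian_fill(arch: pd.DataFrame, n_fill: int) -> pd.DataFrame:
        nonlocal sd
        done, fill_rows = 0, []
        while done < n_fill:
            j_cr = max(float(arch["J"].min()), floor) * cof
            feas = arch[arch["J"] <= j_cr]
            best = arch.loc[arch["J"].idxmin(), names].to_numpy(float)
            use_cov = len(feas) >= p + 2
            if use_cov:
                mean = feas[names].mean().to_numpy(float)
                cov = (4.0 * np.cov(feas[names].to_numpy(float),
                                    rowvar=False)
                       + np.diag((0.25 * sd) ** 2))
                chol = np.linalg.cholesky(cov)
            n_b = min(batch, n_fill - done)
            batch_rows = []
            for i in range(n_b):
                if use_cov and i % 2 == 0:
                    x = mean + chol @ rng.standard_normal(p)
                else:
                    x = best + rng.standard_normal(p) * sd
                batch_rows.append(evaluate(np.clip(x, lo_b, hi_b)))
            fill_rows += batch_rows
            done += n_b
            arch = pd.concat([arch, pd.DataFrame(batch_rows)],
                             ignore_index=True)
            acc = np.mean([r["J"] <= j_cr for r in batch_rows])
            if acc < 0.2:
                sd *= 0.5
            elif acc > 0.6:
                sd *= 1.7
        return pd.DataFrame(fill_rows)

    # iterate trace/walk/fill to a fixpoint: on under-converged surfaces
    # every stage can still lower the optimum, which invalidates earlier
    # feasible points; stop when the optimum is stable and the feasible
    # set is populated enough for range and CV estimates to mean something
    for _round in range(2):
        j_start = max(float(archive["J"].min()), floor)
        for stage in (trace_boundaries, do_walk):
            new = stage(archive)
            if len(new):
                archive = pd.concat([archive, new], ignore_index=True)
        new = gaussian_fill(archive, n_total)
        if len(new):
            archive = pd.concat([archive, new], ignore_index=True)
        j_end = max(float(archive["J"].min()), floor)
        j_cr = j_end * cof
        n_feas = int((archive["J"] <= j_cr).sum())
        if j_end > 0.995 * j_start and n_feas >= 3 * p:
            break
    return CalibrationResult(model=model, archive=archive,
                             param_names=names, spec=result.spec,
                             n_obs=result.n_obs, seed=result.seed,
                             budget=result.budget + n_total)


# ---------------------------------------------------------------------------
# sensitivity screening
# ---------------------------------------------------------------------------

def sensitivity_ranking(model: _CalibratableModel,
                        bounds: dict[str, tuple[float, float]] | None = None,
                        n_samples: int | None = None, seed: int = 0,
                        delta: float = 0.25) -> pd.DataFrame:
    """Morris elementary-effects screening of the composite objective.

    Radial one-at-a-time design on the unit hypercube: for each base point
    the objective change from perturbing each parameter by ``delta`` (in
    normalised units) is recorded; parameters are ranked by the mean
    absolute elementary effect mu*. Degenerate bounds exclude a parameter.
    """
    bounds = bounds or model.bounds
    names = [k for k, (lo, hi) in bounds.items() if hi > lo]
    p = len(names)
    if n_samples is None:
        n_samples = 10 * p
    n_traj = max(2, n_samples // (p + 1))
    rng = np.random.default_rng(seed)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])

    def j_of(unit: np.ndarray) -> float:
        params = dict(zip(names, (lo + unit * (hi - lo)).tolist()))
        try:
            return model.objective(params)
        except Exception:  # noqa: BLE001
            return PENALTY_J

    effects = {k: [] for k in names}
    for _ in range(n_traj):
        base = rng.uniform(0.0, 1.0 - delta, size=p)
        j0 = j_of(base)
        for i, k in enumerate(names):
            pt = base.copy()
            pt[i] += delta
            effects[k].append((j_of(pt) - j0) / delta)
    out = pd.DataFrame({
        "parameter": names,
        "mu_star": [float(np.mean(np.abs(effects[k]))) for k in names],
        "sigma": [float(np.std(effects[k])) for k in names],
    }).sort_values("mu_star", ascending=False).reset_index(drop=True)
    return out
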