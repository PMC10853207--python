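"""Synthetic-data generators with known ground truth.

Every table the pipeline consumes can be generated here from a known
parameter set, so each downstream stage (isotope partitioning, qSIP
calling, laboratory and field calibration, PLS attribution) is testable
against truth without any external data.

The generators emulate the *study design*, not raw instrument output:
7-day dual-isotope incubation respiration curves with replicate noise,
24-fraction CsCl density profiles in which labeled taxa shift toward
heavier densities, and multi-year daily forcing/observation series
produced by the mechanistic model under a known parameter vector.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import (FieldSetup, LabSetup, field_observables,
                        lab_case_trajectory, lab_observables)
from .mend import Forcing, MendParams, MendState, simulate_mend, spin_up
from .qsip import ExtractionMeta, QsipDataset

__all__ = ["SynthConfig", "make_lab_incubation", "make_qsip_dataset",
           "make_field_dataset", "make_pls_dataset", "synthetic_forcing"]


def _default_obs_noise() -> dict[str, float]:
    return {"rh": 0.10, "mbc": 0.10, "active_fraction": 0.10,
            "enz_o": 0.10, "enz_h": 0.10}


@dataclass
class SynthConfig:
    """Ground truth and noise levels for all generators."""

    seed: int = 0
    n_replicates: int = 4
    incubation_days: int = 7
    n_fractions: int = 24
    n_asvs: int = 200
    n_active: int = 20
    density_shift_mean: float = 0.02     # g/ml
    density_noise_sd: float = 0.003      # g/ml
    profile_sd: float = 0.008            # CsCl band width, g/ml
    respiration_noise_cv: float = 0.05
    field_years: int = 7
    observation_noise: dict[str, float] = field(
        default_factory=_default_obs_noise)
    true_params: MendParams = field(default_factory=MendParams)
    lab_setup: LabSetup = field(default_factory=LabSetup)

    def __post_init__(self) -> None:
        if self.n_active > self.n_asvs:
            raise ValueError("n_active cannot exceed n_asvs")
        if (self.density_noise_sd < 0 or self.respiration_noise_cv < 0
                or any(v < 0 for v in self.observation_noise.values())):
            raise ValueError("noise parameters must be nonnegative")
        self.lab_setup.days = self.incubation_days

    def rng(self, stream: str) -> np.random.Generator:
        # stable per-stream child seed (str.hash is salted per process)
        key = zlib.crc32(stream.encode()) % 2 ** 31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size) - sigma ** 2 / 2.0)


# ---------------------------------------------------------------------------
# laboratory incubation
# ---------------------------------------------------------------------------

def make_lab_incubation(cfg: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Daily dual-isotope respiration series for the six incubation cases.

    Returns ``(series, truth)``. ``series`` has one row per treatment x
    straw group x replicate x day with ``total_ugC_g`` and ``c13_ugC_g``
    interval effluxes (µg C/g soil/d). Noise is multiplicative lognormal
    with CV ``respiration_noise_cv``; the same factor multiplies the total
    and 13C channel of a replicate-day (a shared gas-volume error), so the
    sub-pool bound c13 <= total survives noise. ``truth`` carries the
    noise-free series, the full simulator trajectories, the observables
    used for calibration and a substrate-origin tracer run (straw atom
    fraction forced to 1) whose labeled CO2 is exactly the straw-derived
    respiration.
    """
    p = cfg.true_params
    setup = cfg.lab_setup
    rng = cfg.rng("lab")
    rows, truth_rows = [], []
    trajectories: dict = {}
    tracer: dict = {}
    for treatment, warmed in (("control", False), ("warmed", True)):
        for straw in ("none", "c12", "c13"):
            traj = lab_case_trajectory(p, setup, warmed, straw)
            if not np.all(np.isfinite(traj["co2_cum"])):
                raise RuntimeError(
                    f"non-finite simulator output for {treatment}/{straw}: "
                    f"check parameters {p}")
            trajectories[(treatment, straw)] = traj
            total = np.diff(traj["co2_cum"]) * 1000.0   # mg -> µg C/g/d
            c13 = np.diff(traj["co2_cum_labeled"]) * 1000.0
            if straw != "none":
                # pure substrate tracer: unlabeled background, straw
                # atom fraction forced to 1, so the labeled CO2 channel
                # is exactly the straw-derived respiration
                tracer_setup = replace(setup, background_atom13=0.0)
                tw = lab_case_trajectory(p, tracer_setup, warmed, straw,
                                         atom13_override=1.0)
                tracer[(treatment, straw)] = np.diff(
                    tw["co2_cum_labeled"]) * 1000.0
            days = np.arange(1, cfg.incubation_days + 1)
            for rep in range(1, cfg.n_replicates + 1):
                fac = _lognormal_factor(rng, cfg.respiration_noise_cv,
                                        cfg.incubation_days)
                for i, day in enumerate(days):
                    rows.append({"treatment": treatment, "straw_group": straw,
                                 "replicate": f"r{rep}", "day": int(day),
                                 "total_ugC_g": total[i] * fac[i],
                                 "c13_ugC_g": c13[i] * fac[i]})
                    truth_rows.append({
                        "treatment": treatment, "straw_group": straw,
                        "replicate": f"r{rep}", "day": int(day),
                        "total_ugC_g": total[i], "c13_ugC_g": c13[i]})
    truth = {
        "series": pd.DataFrame(truth_rows),
        "trajectories": trajectories,
        "substrate_respiration_ugC_g": tracer,
        "observables": lab_observables(p, setup),
        "params": p,
        "setup": setup,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# qSIP density-fraction dataset
# ---------------------------------------------------------------------------

def _moment_corrected_profile(densities: np.ndarray, mu: float,
                              sd: float) -> np.ndarray:
    """Discretized Gaussian band whose weighted mean is exactly ``mu``.

    A plain Gaussian evaluated on the fraction grid has a first moment
    slightly off ``mu``; a linear tilt restores it so that zero-noise
    density shifts are recovered exactly by the weighted-density
    estimator.
    """
    w = np.exp(-0.5 * ((densities - mu) / sd) ** 2)
    w /= w.sum()
    m = float(w @ densities)
    var = float(w @ (densities - m) ** 2)
    if var > 0:
        w = w * (1.0 + (mu - m) * (densities - m) / var)
        w = np.maximum(w, 0.0)   # clips only ~1e-30 tail weights
        w /= w.sum()
    return w


def make_qsip_dataset(cfg: SynthConfig,
                      meta: ExtractionMeta | None = None,
                      ) -> tuple[QsipDataset, dict]:
    """Per-fraction density/qPCR records plus an ASV x fraction matrix.

    Each replicate x isotope-label sample draws, for every ASV, a
    Gaussian abundance band over the 1.66-1.77 g/ml density grid. The
    ``n_active`` labeled ASVs get their 13C-sample band centre increased
    by N(density_shift_mean, density_noise_sd); all per-sample band
    centres additionally jitter by N(0, density_noise_sd). Per-fraction
    qPCR totals are the summed profiles times a scale factor.
    """
    if cfg.density_shift_mean <= 0:
        raise ValueError("density_shift_mean must be positive")
    meta = meta or ExtractionMeta()
    rng = cfg.rng("qsip")
    densities = np.linspace(1.66, 1.77, cfg.n_fractions)
    asv_ids = [f"ASV{i:04d}" for i in range(cfg.n_asvs)]
    active = np.zeros(cfg.n_asvs, bool)
    active[rng.choice(cfg.n_asvs, cfg.n_active, replace=False)] = True
    base_mu = rng.uniform(1.69, 1.72, cfg.n_asvs)
    base_abundance = np.exp(rng.normal(np.log(1000.0), 1.0, cfg.n_asvs))
    qpcr_scale = 0.01  # copies/µl per sequence count

    frac_rows, count_cols = [], {}
    for rep in range(1, cfg.n_replicates + 1):
        for label in ("c12", "c13"):
            sid = f"w_{label}_r{rep}"
            jitter = rng.normal(0.0, cfg.density_noise_sd, cfg.n_asvs)
            shift = np.zeros(cfg.n_asvs)
            if label == "c13":
                shift[active] = rng.normal(cfg.density_shift_mean,
                                           cfg.density_noise_sd,
                                           cfg.n_active)
            profiles = np.vstack([
                base_abundance[a] * _moment_corrected_profile(
                    densities, base_mu[a] + jitter[a] + shift[a],
                    cfg.profile_sd)
                for a in range(cfg.n_asvs)])
            totals = profiles.sum(axis=0) * qpcr_scale
            for i in range(cfg.n_fractions):
                frac_rows.append({
                    "sample_id": sid, "treatment": "warmed",
                    "replicate": f"r{rep}", "isotope_label": label,
                    "fraction_index": i + 1,
                    "density_g_ml": densities[i],
                    "qpcr_copies_per_ul": totals[i]})
                count_cols[f"{sid}:{i + 1}"] = profiles[:, i]
    fractions = pd.DataFrame(frac_rows)
    counts = pd.DataFrame(count_cols, index=asv_ids)
    dataset = QsipDataset(fractions=fractions, counts=counts, meta=meta)
    truth = {"active": pd.Series(active, index=asv_ids),
             "base_density": pd.Series(base_mu, index=asv_ids),
             "densities": densities, "qpcr_scale": qpcr_scale}
    return dataset, truth


# ---------------------------------------------------------------------------
# field forcing and observations
# ---------------------------------------------------------------------------

def synthetic_forcing(cfg: SynthConfig, *, warming_offset_c: float = 0.0,
                      litter_on: bool = True) -> Forcing:
    """Sinusoidal-plus-noise daily forcing for ``field_years`` years.

    GPP-derived litter input is converted from g C/m2/d to mg C/g soil/h
    assuming a 15-cm, 1.2 g/cm3 soil layer and that half the GPP reaches
    the soil as litter.
    """
    rng = cfg.rng("forcing")
    n_days = int(cfg.field_years * 365)
    doy = np.arange(n_days)
    temp = (15.0 + 10.0 * np.sin(2 * np.pi * (doy - 120) / 365.0)
            + rng.normal(0, 1.5, n_days) + warming_offset_c)
    moisture = np.clip(0.25 + 0.08 * np.sin(2 * np.pi * (doy - 60) / 365.0)
                       + rng.normal(0, 0.02, n_days), 0.02, 0.6)
    ph = np.full(n_days, 6.64)
    gpp = np.maximum(0.0, 3.0 + 3.0 * np.sin(2 * np.pi * (doy - 120) / 365.0)
                     + rng.normal(0, 0.5, n_days))       # g C/m2/d
    soil_g_per_m2 = 0.15 * 1.2e6                          # 15 cm x 1.2 g/cm3
    litter = 0.5 * gpp * 1000.0 / soil_g_per_m2 / 24.0   # mg C/g soil/h
    if not litter_on:
        litter = np.zeros(n_days)
    return Forcing(dt=24.0, temp_c=temp, moisture=moisture, ph=ph,
                   litter_rate=litter,
                   litter_atom13=np.full(n_days, 0.0108))


def make_field_dataset(cfg: SynthConfig, *, spin_up_years: float = 20.0,
                       step_h: float = 6.0, sparse_every_d: int = 30,
                       gene_scales: tuple[float, float] = (3.5, 0.8),
                       ) -> tuple[FieldSetup, dict, dict]:
    """Forcing plus noisy field observations from a known parameter set.

    Returns ``(setup, observations, truth)``. Gene abundances are the
    enzyme concentrations times an arbitrary positive scale (and noise),
    which is why enzyme objectives are correlation-based. Rh is observed
    daily; microbial biomass, active fraction and gene abundances every
    ``sparse_every_d`` days.
    """
    p = cfg.true_params
    forcing = synthetic_forcing(cfg)
    initial = spin_up(p, forcing, years=spin_up_years, step_h=24.0)
    if np.any(initial.pools < -1e-9):
        raise RuntimeError("negative pools after spin-up; reduce step size")
    setup = FieldSetup(forcing=forcing, initial=initial, step_h=step_h,
                       sparse_every_d=sparse_every_d)
    clean = field_observables(p, setup)
    rng = cfg.rng("field")
    observations = {}
    for var, series in clean.items():
        cv = cfg.observation_noise.get(var, 0.0)
        noisy = series * _lognormal_factor(rng, cv, len(series))
        if var == "enz_o":
            noisy = noisy * gene_scales[0]
        elif var == "enz_h":
            noisy = noisy * gene_scales[1]
        observations[var] = noisy
    truth = {"observables": clean, "params": p, "gene_scales": gene_scales,
             "initial": initial}
    return setup, observations, truth


# ---------------------------------------------------------------------------
# PLS benchmark dataset
# ---------------------------------------------------------------------------

def make_pls_dataset(cfg: SynthConfig, *, n_samples: int = 40,
                     n_predictors: int = 8, n_loading: int = 3,
                     n_latent: int = 1, noise_sd: float = 0.3,
                     loading: float = 1.0,
                     ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Latent-factor predictors and response with known loading structure.

    The first ``n_loading`` predictors load on the latent factor(s) that
    generate the response; the rest are pure noise. Returns
    ``(X, y, true_loading_mask)``.
    """
    if n_predictors < 2:
        raise ValueError("need at least two predictors")
    rng = cfg.rng("pls")
    z = rng.normal(0.0, 1.0, (n_samples, n_latent))
    x = rng.normal(0.0, 1.0, (n_samples, n_predictors))
    mask = np.zeros(n_predictors, bool)
    mask[:n_loading] = True
    for j in range(n_loading):
        x[:, j] = loading * z[:, j % n_latent] + rng.normal(
            0.0, noise_sd, n_samples)
    y = z.sum(axis=1) + rng.normal(0.0, noise_sd, n_samples)
    cols = [f"x{j}" for j in range(n_predictors)]
    return pd.DataFrame(x, columns=cols), y, mask
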