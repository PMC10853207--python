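"""Headspace-gas conversion and isotope partitioning of soil respiration.

Implements the two-pool mixing arithmetic used to split respired CO2 from a
straw-amended incubation into straw-derived and native soil C, and the
priming/replenishment bookkeeping that follows from it.

Conventions
-----------
* delta13C values are per-mil relative to VPDB (ratio 0.0111802); mixing is
  performed in atom fraction, which is exact, rather than in delta units.
* "Primed C" is the extra native soil C respired relative to the no-straw
  basal incubation: primed = total(with straw) - straw-derived - basal.
* Positive priming is a soil-C loss, so the net effect of a litter addition
  is net = replenishment - primed with the default sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VPDB_RATIO",
    "R_GAS",
    "GasSample",
    "IsotopeMeasurement",
    "PrimingResult",
    "headspace_to_carbon",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "substrate_fraction",
    "partition_respiration",
    "net_effect",
]

VPDB_RATIO = 0.0111802   # 13C/12C of the VPDB standard
R_GAS = 8.314            # J/K/mol

# composition of the oat-straw substrate used as the default amendment
STRAW_C_PERCENT = 40.10
STRAW_N_PERCENT = 1.70
STRAW_ATOM13 = 0.751     # atom fraction 13C of the labeled straw


def straw_cn_ratio(c_percent: float = STRAW_C_PERCENT,
                   n_percent: float = STRAW_N_PERCENT) -> float:
    """Mass C:N ratio of the amendment substrate."""
    if n_percent <= 0:
        raise ValueError("N content must be positive")
    return c_percent / n_percent


@dataclass
class GasSample:
    """One headspace measurement (CO2 or 13CO2 mixing ratio)."""

    ppm: float
    headspace_volume_ml: float = 25.0
    pressure_kpa: float = 101.0
    temperature_k: float = 298.0

    def __post_init__(self) -> None:
        if self.ppm < 0:
            raise ValueError("ppm must be nonnegative")
        for name in ("headspace_volume_ml", "pressure_kpa", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def headspace_to_carbon(sample: GasSample) -> float:
    """Moles of CO2 (µmol) in the headspace from the ideal gas law.

    n = P * (V * ppm) / (R * T) with the partial volume V*ppm in m³ and
    pressure in Pa; the result is returned in µmol.
    """
    v_m3 = sample.headspace_volume_ml * 1e-6 * sample.ppm * 1e-6
    n_mol = sample.pressure_kpa * 1e3 * v_m3 / (R_GAS * sample.temperature_k)
    return n_mol * 1e6


def delta_to_atom_fraction(delta: float | np.ndarray) -> float | np.ndarray:
    """Convert per-mil delta13C to atom fraction 13C."""
    r = VPDB_RATIO * (1.0 + np.asarray(delta, float) / 1000.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(af: float | np.ndarray) -> float | np.ndarray:
    """Convert atom fraction 13C to per-mil delta13C."""
    af = np.asarray(af, float)
    r = af / (1.0 - af)
    return (r / VPDB_RATIO - 1.0) * 1000.0


@dataclass
class IsotopeMeasurement:
    """Mixing endmembers and the mixture for one day's respired CO2.

    ``delta_c``: basal (no-straw) CO2; ``delta_t``: CO2 with labeled straw;
    ``delta_l``: the labeled straw itself. Values are per-mil delta13C
    unless ``as_atom_fraction`` is set, in which case they are atom
    fractions directly.
    """

    delta_c: float
    delta_t: float
    delta_l: float
    as_atom_fraction: bool = False

    def atom_fractions(self) -> tuple[float, float, float]:
        if self.as_atom_fraction:
            return self.delta_c, self.delta_t, self.delta_l
        return tuple(delta_to_atom_fraction(x)
                     for x in (self.delta_c, self.delta_t, self.delta_l))


def substrate_fraction(m: IsotopeMeasurement) -> float:
    """Fraction of respired CO2-C derived from the labeled substrate.

    Two-pool mixing: f = (A_C - A_T) / (A_C - A_L) evaluated in atom
    fraction. Results slightly outside [0, 1] (replicate noise) are clamped
    with a warning; equal endmembers are rejected.
    """
    a_c, a_t, a_l = m.atom_fractions()
    if np.isclose(a_c, a_l):
        raise ValueError("mixing endmembers are equal; fraction undefined")
    f = (a_c - a_t) / (a_c - a_l)
    if f < 0.0 or f > 1.0:
        warnings.warn(f"substrate fraction {f:.4f} outside [0, 1]; clamped",
                      stacklevel=2)
        f = min(1.0, max(0.0, f))
    return float(f)


@dataclass
class PrimingResult:
    """Per-replicate cumulative respiration partition (µg C/g soil)."""

    table: pd.DataFrame  # columns: treatment, replicate, total_respiration,
    #                      substrate_derived, basal, primed, priming_pct_basal

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("treatment")[
            ["total_respiration", "substrate_derived", "basal", "primed",
             "priming_pct_basal"]]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")


def partition_respiration(series: pd.DataFrame,
                          straw_atom13: float | None = None,
                          fractions: dict[int, float] | pd.Series | None = None,
                          labeled_group: str = "c13",
                          basal_group: str = "none") -> PrimingResult:
    """Partition cumulative respiration into substrate-derived, basal and
    primed components, per replicate and treatment.

    Parameters
    ----------
    series:
        Long table with columns ``treatment, straw_group, replicate, day,
        total_ugC_g`` and (unless ``fractions`` is given) ``c13_ugC_g``.
    straw_atom13:
        Atom fraction 13C of the labeled straw (the heavy mixing
        endmember). When given, a per-day, per-replicate substrate
        fraction is computed by two-pool mixing from the series' own 13C
        channels: the mixture's atom fraction is ``c13/total`` in the
        straw group, the light endmember is the paired basal replicate's
        ``c13/total`` on the same day.
    fractions:
        Pre-computed per-day substrate fractions (e.g. from
        :func:`substrate_fraction` applied to delta13C measurements);
        applied day-by-day before summation. Exactly one of
        ``straw_atom13`` / ``fractions`` must be provided.
    """
    _require_columns(series, ("treatment", "straw_group", "replicate", "day",
                              "total_ugC_g"))
    if (straw_atom13 is None) == (fractions is None):
        raise ValueError("provide exactly one of straw_atom13 or fractions")
    rows = []
    for treat, df_t in series.groupby("treatment", sort=True):
        straw = df_t[df_t.straw_group == labeled_group]
        basal = df_t[df_t.straw_group == basal_group]
        if basal.empty:
            raise ValueError(f"no basal (no-straw) group for {treat!r}")
        if straw.empty:
            raise ValueError(f"no {labeled_group!r} straw group for {treat!r}")
        basal_by_rep = basal.groupby("replicate")["total_ugC_g"].sum()
        for rep, df_r in straw.groupby("replicate", sort=True):
            if rep not in basal_by_rep.index:
                raise ValueError(f"replicate {rep!r} missing from basal group")
            df_r = df_r.sort_values("day")
            total_by_day = df_r["total_ugC_g"].to_numpy(float)
            total = float(total_by_day.sum())
            if fractions is not None:
                fr = np.array([fractions[d] for d in df_r["day"]])
            else:
                _require_columns(df_r, ("c13_ugC_g",))
                bas_r = basal[basal.replicate == rep].set_index("day")
                a_t = df_r["c13_ugC_g"].to_numpy(float) / total_by_day
                bt = bas_r.loc[df_r["day"], "total_ugC_g"].to_numpy(float)
                a_c = bas_r.loc[df_r["day"], "c13_ugC_g"].to_numpy(float) / bt
                fr = np.array([
                    substrate_fraction(IsotopeMeasurement(
                        c, t, straw_atom13, as_atom_fraction=True))
                    for c, t in zip(a_c, a_t)])
            substrate = float((total_by_day * fr).sum())
            basal_tot = float(basal_by_rep.loc[rep])
            primed = total - substrate - basal_tot
            rows.append({
                "treatment": treat, "replicate": rep,
                "total_respiration": total, "substrate_derived": substrate,
                "basal": basal_tot, "primed": primed,
                "priming_pct_basal": 100.0 * primed / basal_tot
                if basal_tot else np.nan,
            })
    return PrimingResult(pd.DataFrame(rows))


def net_effect(added_c: float, substrate_respired: float, primed: float,
               sign_convention: str = "loss") -> tuple[float, float]:
    """Replenishment and net soil-C effect of a litter addition.

    replenishment = added_c - substrate_respired (litter C left in soil).
    With the default ``loss`` convention positive priming is a native-C
    loss, so net = replenishment - primed; the ``gain`` convention returns
    net = replenishment + primed for workflows where priming is recorded
    with the opposite sign.
    """
    if substrate_respired > added_c:
        raise ValueError("substrate respiration exceeds added C (mass balance)")
    replenishment = added_c - substrate_respired
    if sign_convention == "loss":
        net = replenishment - primed
    elif sign_convention == "gain":
        net = replenishment + primed
    else:
        raise ValueError("sign_convention must be 'loss' or 'gain'")
    return replenishment, net
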