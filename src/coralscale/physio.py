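"""From raw incubation measurements to per-colony physiological rates.

Two measurement streams feed this module:

* **Respirometry traces** — O2 concentration versus time in a closed
  chamber.  After discarding the stabilization transient, the linear
  slope (mg L⁻¹ h⁻¹), corrected by the blank-chamber slope and scaled by
  chamber volume, gives the whole-colony O2 flux (mg h⁻¹).  The light
  phase measures net photosynthesis, the dark phase respiration; gross
  photosynthesis is net plus respiration.
* **Alkalinity pairs** — total alkalinity at the start and end of an
  incubation.  Precipitating one mole of CaCO3 removes two moles of
  alkalinity, so the control-corrected drop ΔAT over Δt hours gives the
  calcification rate −ΔAT/(2Δt), converted through seawater density,
  chamber volume and the CaCO3 molar mass to g CaCO3 cm⁻² h⁻¹.

Quality control removes colonies with negative calcification
(dissolution), tank temperature outside the 27–31 °C window at any
point, or an O2-trace fit with R² below 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhysioConstants",
    "O2Fit",
    "Rates",
    "trim_stabilization",
    "fit_o2_slope",
    "o2_flux",
    "derive_rates",
    "calcification_rate",
    "qc_filter",
    "process_study",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physical constants and QC thresholds.

    rho_sw
        Seawater density, kg L⁻¹ (bridges the per-kg alkalinity units
        to the per-litre chamber volume).
    molar_mass_caco3
        g mol⁻¹, converts the molar calcification rate to mass.
    r2_min
        Minimum R² of the O2-versus-time linear fit.
    temp_window
        Acceptable tank temperature range, °C.
    stabilization_min
        Minutes removed from the start of each trace.
    """

    rho_sw: float = 1.025
    molar_mass_caco3: float = 100.0869
    r2_min: float = 0.8
    temp_window: tuple[float, float] = (27.0, 31.0)
    stabilization_min: float = 30.0

    def __post_init__(self) -> None:
        if self.rho_sw <= 0 or self.molar_mass_caco3 <= 0:
            raise ValueError("physical constants must be positive")
        if not self.temp_window[0] <= self.temp_window[1]:
            raise ValueError("temp_window must be ordered (low, high)")


class O2Fit(NamedTuple):
    slope: float  # mg L^-1 h^-1
    r_squared: float


class Rates(NamedTuple):
    respiration: float          # mg O2 h^-1, positive magnitude
    net_photosynthesis: float   # mg O2 h^-1
    gross_photosynthesis: float  # mg O2 h^-1


def trim_stabilization(trace: pd.DataFrame, window_min: float = 30.0) -> pd.DataFrame:
    """Drop all records earlier than ``window_min`` minutes.

    The boundary point (time exactly equal to the window) is kept.
    Raises if fewer than 3 points remain — too short to fit a slope.
    """
    out = trace[trace["time_h"] >= window_min / 60.0]
    if len(out) < 3:
        raise ValueError(
            f"trace too short: {len(out)} points remain after trimming "
            f"{window_min} min from a {trace['time_h'].max():.2f} h trace"
        )
    return out.reset_index(drop=True)


def fit_o2_slope(trace: pd.DataFrame) -> O2Fit:
    """Ordinary least-squares slope of O2 concentration against time."""
    t = np.asarray(trace["time_h"], dtype=float)
    y = np.asarray(trace["o2_mg_l"], dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to fit a slope")
    if np.ptp(t) == 0:
        raise ValueError("zero time-variance: all timestamps identical")
    if np.ptp(y) == 0:
        # Perfectly constant concentration: slope 0, R^2 undefined.
        return O2Fit(0.0, float("nan"))
    res = stats.linregress(t, y)
    return O2Fit(float(res.slope), float(res.rvalue ** 2))


def o2_flux(slope: float, control_slope: float, chamber_volume_l: float) -> float:
    """Whole-colony O2 flux (mg h⁻¹); positive = net O2 production."""
    if chamber_volume_l <= 0:
        raise ValueError("chamber volume must be positive")
    return (slope - control_slope) * chamber_volume_l


def derive_rates(light_flux: float, dark_flux: float) -> Rates:
    """Respiration, net and gross photosynthesis from the two fluxes.

    The dark flux is O2 consumption, so respiration = −dark_flux; the
    light flux already nets production against respiration, so
    net = light_flux and gross = net + respiration.  A positive dark
    flux (net O2 production in darkness) is biologically implausible
    and raises; callers flag and drop the record.
    """
    if dark_flux > 0:
        raise ValueError(
            f"dark-phase O2 flux {dark_flux:+.4g} mg/h is positive (implausible)"
        )
    respiration = -dark_flux
    net = light_flux
    return Rates(respiration, net, net + respiration)


def calcification_rate(
    chem: pd.Series | dict,
    control: pd.Series | dict | None,
    area_cm2: float,
    k: PhysioConstants = PhysioConstants(),
) -> tuple[float, float]:
    """Calcification from an alkalinity pair: (g cm⁻² h⁻¹, whole-colony g h⁻¹).

    The alkalinity drop is control-corrected (ΔAT_sample − ΔAT_control,
    both in μmol kg⁻¹) and divided by twice the duration, then carried
    through the unit chain: × ρ_sw (kg L⁻¹) × chamber volume (L) gives
    μmol CaCO3 h⁻¹; × 10⁻⁶ → mol h⁻¹; ÷ area → mol cm⁻² h⁻¹; × molar
    mass → g cm⁻² h⁻¹.
    """
    if area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    dt = float(chem["delta_t_h"])
    if dt <= 0:
        raise ValueError("incubation duration must be positive")
    drop = float(chem["at_start_umol_kg"]) - float(chem["at_end_umol_kg"])
    if control is not None:
        drop -= float(control["at_start_umol_kg"]) - float(control["at_end_umol_kg"])
    umol_h = drop / (2.0 * dt) * k.rho_sw * float(chem["chamber_volume_l"])
    g_h = umol_h * 1e-6 * k.molar_mass_caco3
    return g_h / area_cm2, g_h


_QC_RULES = ("negative_calcification", "temperature_window", "r_squared", "positive_dark_flux")


def qc_filter(
    records: pd.DataFrame, k: PhysioConstants = PhysioConstants()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three data-quality rules; return (retained, rejection log).

    Expects columns ``calcification_g_h``, ``temp_ok`` (bool, whether
    every incubation temperature stayed inside the window — computed by
    the caller who still has the raw traces), ``min_r_squared`` and,
    optionally, ``dark_flux_positive``.  Each removal is logged with the
    rule that fired; a colony failing several rules is logged once per
    rule.  The operation is idempotent.
    """
    df = records.copy()
    reasons = []
    bad = pd.Series(False, index=df.index)
    if "calcification_g_h" in df:
        m = df["calcification_g_h"] < 0
        bad |= m
        for cid in df.loc[m, "colony_id"]:
            reasons.append({"colony_id": cid, "rule": "negative_calcification"})
    if "temp_ok" in df:
        m = ~df["temp_ok"].astype(bool)
        bad |= m
        for cid in df.loc[m, "colony_id"]:
            reasons.append({"colony_id": cid, "rule": "temperature_window"})
    if "min_r_squared" in df:
        m = ~(df["min_r_squared"] >= k.r2_min)  # NaN R^2 also fails
        bad |= m
        for cid in df.loc[m, "colony_id"]:
            reasons.append({"colony_id": cid, "rule": "r_squared"})
    if "dark_flux_positive" in df:
        m = df["dark_flux_positive"].astype(bool)
        bad |= m
        for cid in df.loc[m, "colony_id"]:
            reasons.append({"colony_id": cid, "rule": "positive_dark_flux"})
    retained = df.loc[~bad].reset_index(drop=True)
    log = pd.DataFrame(reasons, columns=["colony_id", "rule"])
    return retained, log


def _control_slopes(traces: pd.DataFrame, k: PhysioConstants) -> dict[tuple[int, str], float]:
    """Mean blank-chamber slope per (set, phase)."""
    out: dict[tuple[int, str], float] = {}
    ctrl = traces[traces["is_control"].astype(bool)]
    for (set_id, phase), grp in ctrl.groupby(["set_id", "phase"]):
        slopes = []
        for _, tr in grp.groupby("colony_id"):
            trimmed = trim_stabilization(tr, k.stabilization_min)
            slopes.append(fit_o2_slope(trimmed).slope)
        out[(set_id, phase)] = float(np.mean(slopes))
    return out


def _control_drops(chems: pd.DataFrame) -> dict[int, float]:
    """Mean control alkalinity drop per set (μmol kg⁻¹)."""
    out: dict[int, float] = {}
    ctrl = chems[chems["is_control"].astype(bool)]
    for set_id, grp in ctrl.groupby("set_id"):
        out[set_id] = float(
            (grp["at_start_umol_kg"] - grp["at_end_umol_kg"]).mean()
        )
    return out


def process_study(
    metadata: pd.DataFrame,
    traces: pd.DataFrame,
    chemistry: pd.DataFrame,
    k: PhysioConstants = PhysioConstants(),
    require_controls: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full extraction: traces + chemistry + metadata → tidy rate table.

    Returns ``(retained, rejection_log)``.  ``retained`` has one row per
    colony with columns species, size_class, area_cm2, calcification_g_h
    (whole colony), calcification_g_cm2_h, respiration_mg_h,
    net_photo_mg_h, gross_photo_mg_h.  Rejections carry the rule that
    fired (including trace-level failures such as a positive dark flux).
    """
    ctrl_slopes = _control_slopes(traces, k)
    ctrl_drop = _control_drops(chemistry)
    if require_controls and not ctrl_slopes:
        raise ValueError(
            "no control (blank-chamber) traces found; pass require_controls=False "
            "to assume zero background drift"
        )
    rows = []
    sample_traces = traces[~traces["is_control"].astype(bool)]
    sample_chem = chemistry[~chemistry["is_control"].astype(bool)].set_index("colony_id")
    meta = metadata.set_index("colony_id")
    for colony_id, grp in sample_traces.groupby("colony_id"):
        if colony_id not in meta.index:
            raise KeyError(f"trace colony {colony_id!r} missing from metadata")
        m = meta.loc[colony_id]
        row: dict = {
            "colony_id": colony_id,
            "species": m["species"],
            "size_class": m["size_class"],
            "area_cm2": float(m["surface_area_3d_cm2"]),
        }
        fluxes, r2s, temps_ok = {}, [], True
        for phase, tr in grp.groupby("phase"):
            trimmed = trim_stabilization(tr, k.stabilization_min)
            fit = fit_o2_slope(trimmed)
            set_id = tr["set_id"].iloc[0]
            key = (set_id, phase)
            if key in ctrl_slopes:
                c = ctrl_slopes[key]
            elif require_controls:
                raise ValueError(f"missing control trace for set {set_id}, phase {phase}")
            else:
                c = 0.0
            fluxes[phase] = o2_flux(fit.slope, c, float(tr["chamber_volume_l"].iloc[0]))
            r2s.append(fit.r_squared)
            lo, hi = k.temp_window
            if not bool(tr["temperature_c"].between(lo, hi).all()):
                temps_ok = False
        row["min_r_squared"] = float(np.min(r2s)) if r2s else float("nan")
        row["temp_ok"] = temps_ok
        row["dark_flux_positive"] = fluxes.get("dark", 0.0) > 0
        if not row["dark_flux_positive"] and "light" in fluxes and "dark" in fluxes:
            rates = derive_rates(fluxes["light"], fluxes["dark"])
            row["respiration_mg_h"] = rates.respiration
            row["net_photo_mg_h"] = rates.net_photosynthesis
            row["gross_photo_mg_h"] = rates.gross_photosynthesis
        if colony_id in sample_chem.index:
            chem = sample_chem.loc[colony_id]
            if isinstance(chem, pd.DataFrame):  # several pairs: use the first
                chem = chem.iloc[0]
            set_id = chem["set_id"]
            ctrl = None
            if set_id in ctrl_drop:
                ctrl = {
                    "at_start_umol_kg": ctrl_drop[set_id],
                    "at_end_umol_kg": 0.0,
                }
            elif require_controls:
                raise ValueError(f"missing control chemistry for set {set_id}")
            per_area, whole = calcification_rate(chem, ctrl, row["area_cm2"], k)
            row["calcification_g_cm2_h"] = per_area
            row["calcification_g_h"] = whole
        rows.append(row)
    table = pd.DataFrame(rows)
    retained, log = qc_filter(table, k)
    drop_cols = ["temp_ok", "dark_flux_positive"]
    retained = retained.drop(columns=[c for c in drop_cols if c in retained])
    return retained, log
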