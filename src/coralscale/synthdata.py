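"""Synthetic study-data generator with known ground truth.

Every downstream stage of the package (rate extraction, hierarchical
scaling fit, community upscaling) is verifiable by parameter recovery
against the truth values emitted here.  The generator emulates the
statistical structure of a six-taxon coral incubation study:

* per-colony physiological rates that are log-log linear in live 3D
  surface area, with correlated species-level deviations of intercept
  and slope and lognormal residual noise;
* respirometry O2 traces that are linear in time after an initial
  stabilization transient, with Gaussian sensor noise;
* paired start/end total-alkalinity samples whose drop encodes the
  colony's calcification rate through the alkalinity-anomaly relation
  (an exact round trip with :func:`coralscale.physio.calcification_rate`);
* a genus-level coral-cover trajectory that collapses from ~50% to ~3%
  across a disturbance and then recovers;
* a single right-skewed (lognormal) colony planar-area pool shared by
  all genera.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "GENERA",
    "TruthParams",
    "ScenarioConfig",
    "gen_species_deviations",
    "gen_colonies",
    "gen_study",
    "gen_respirometry_trace",
    "gen_incubation_chemistry",
    "gen_cover_series",
    "gen_size_distribution",
    "write_inputs",
]

#: The six focal reef-building taxa, in fixed order.
SPECIES = (
    "Acropora hyacinthus",
    "Astrea curta",
    "Montipora verrilli",
    "Napopora irregularis",
    "Pocillopora verrucosa",
    "Porites spp.",
)

#: Genus labels used by cover time series; one-to-one with SPECIES.
GENERA = ("Acropora", "Astrea", "Montipora", "Napopora", "Pocillopora", "Porites")

# Chamber volume (L) by visual size class, matching the incubation setup.
CHAMBER_VOLUME_L = {"S1": 0.5, "S2": 1.0, "S3": 4.0}

# Molar mass of CaCO3 used throughout (g mol^-1).
MOLAR_MASS_CACO3 = 100.0869
RHO_SW_KG_L = 1.025


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of one rate's scaling law.

    The observation model is

        ln R_i = (ln_alpha + zeta[s,1]) + (beta + zeta[s,2]) * ln x_i + eps_i

    with ``eps_i ~ N(0, sigma)`` and species deviations ``zeta_s`` drawn
    from a bivariate Gaussian with standard deviations ``sigma_zeta`` and
    correlation ``rho``.

    Defaults are realistic for whole-colony coral calcification in
    g CaCO3 h^-1 against 3D surface area in cm^2.
    """

    ln_alpha: float = -6.126
    beta: float = 0.881
    sigma: float = 0.3
    sigma_zeta: tuple[float, float] = (0.613, 0.075)
    rho: float = -0.58
    n_species: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if len(self.sigma_zeta) != 2 or any(s < 0 for s in self.sigma_zeta):
            raise ValueError(f"sigma_zeta must be two non-negative reals, got {self.sigma_zeta}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Community-scaling scenario: cover trajectory and size pool.

    ``size_dist_params`` are the (log-mean, log-SD) of the lognormal
    colony planar-area pool in cm²; the source distribution's shape is
    not published, so these defaults are placeholders chosen once
    (median 150 cm², right-skewed) and should be overridden when real
    size data are available.
    """

    year_start: int = 2004
    year_end: int = 2017
    disturbance_year: int = 2010
    recovery_year: int = 2016
    cover_start_pct: float = 50.0
    cover_min_pct: float = 3.0
    size_dist_params: tuple[float, float] = (math.log(150.0), 0.8)
    reps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cover_min_pct <= self.cover_start_pct <= 100.0:
            raise ValueError(
                "need 0 <= cover_min_pct <= cover_start_pct <= 100, got "
                f"({self.cover_min_pct}, {self.cover_start_pct})"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.size_dist_params[1] < 0:
            raise ValueError("size-distribution log-SD must be >= 0")
        if not (self.year_start <= self.disturbance_year <= self.year_end):
            raise ValueError("disturbance_year must fall inside the year range")


def _species_names(n: int) -> list[str]:
    if n == len(SPECIES):
        return list(SPECIES)
    return [f"species_{i + 1}" for i in range(n)]


def species_covariance(sigma_zeta: tuple[float, float], rho: float) -> np.ndarray:
    """2x2 covariance of the species (intercept, slope) deviations."""
    s1, s2 = sigma_zeta
    cov = np.array([[s1 ** 2, rho * s1 * s2], [rho * s1 * s2, s2 ** 2]])
    # Positive semi-definiteness can only fail through an out-of-range rho.
    if abs(rho) > 1.0:
        raise ValueError(
            f"implied covariance not positive semi-definite: rho={rho}, SDs={sigma_zeta}"
        )
    return cov


def gen_species_deviations(truth: TruthParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-species (intercept, slope) deviations.

    Returns a frame with columns ``species``, ``zeta_intercept``,
    ``zeta_slope``; rows are drawn from the bivariate Gaussian implied
    by ``truth.sigma_zeta`` and ``truth.rho``.  Degenerate settings are
    honoured exactly: zero SDs give zero deviations, ``rho = ±1``
    collapses the draw onto the corresponding line.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    cov = species_covariance(truth.sigma_zeta, truth.rho)
    # Cholesky-style construction that survives the degenerate cases.
    s1, s2 = truth.sigma_zeta
    z = rng.standard_normal((truth.n_species, 2))
    zeta1 = s1 * z[:, 0]
    zeta2 = s2 * (truth.rho * z[:, 0] + math.sqrt(max(0.0, 1.0 - truth.rho ** 2)) * z[:, 1])
    assert cov.shape == (2, 2)
    return pd.DataFrame(
        {
            "species": _species_names(truth.n_species),
            "zeta_intercept": zeta1,
            "zeta_slope": zeta2,
        }
    )


def gen_colonies(
    truth: TruthParams,
    n_per_species: int = 12,
    area_range_cm2: tuple[float, float] = (10.0, 2000.0),
    seed: int | None = None,
    rate_name: str = "rate",
) -> pd.DataFrame:
    """Simulate one rate's colony table with ground truth attached.

    Areas are log-uniform over ``area_range_cm2`` (even coverage in log
    space, which is where the regression operates).  Both the noiseless
    ("true") and noisy ("obs") log-rates are stored, together with the
    species deviations used, so least-squares or Bayesian recovery can
    be checked exactly.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    lo, hi = area_range_cm2
    if not (0 < lo <= hi):
        raise ValueError(f"area range must be positive and non-empty, got {area_range_cm2}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    dev = gen_species_deviations(truth, rng)
    rows = []
    for s_idx, row in dev.iterrows():
        ln_area = rng.uniform(math.log(lo), math.log(hi), size=n_per_species)
        # Species-line expectation, then the colony's realized rate: the
        # lognormal residual is biological colony-to-colony scatter, so
        # it belongs to the colony's actual metabolism (what incubation
        # measurements encode), not to measurement error.
        mu_ln = (truth.ln_alpha + row.zeta_intercept) + (truth.beta + row.zeta_slope) * ln_area
        true_ln = mu_ln + truth.sigma * rng.standard_normal(n_per_species)
        for j in range(n_per_species):
            area = math.exp(ln_area[j])
            rows.append(
                {
                    "colony_id": f"{row.species.split()[0][:4].upper()}_{s_idx}_{j:03d}",
                    "species": row.species,
                    "size_class": size_class_of(area),
                    "surface_area_3d_cm2": area,
                    "zeta_intercept": row.zeta_intercept,
                    "zeta_slope": row.zeta_slope,
                    f"mu_log_{rate_name}": mu_ln[j],
                    f"true_log_{rate_name}": true_ln[j],
                    f"true_{rate_name}": math.exp(true_ln[j]),
                }
            )
    return pd.DataFrame(rows)


def size_class_of(area_cm2: float) -> str:
    """Visual size class from area: S1 <100, S2 100-400, S3 >400 cm²."""
    if area_cm2 < 100.0:
        return "S1"
    if area_cm2 <= 400.0:
        return "S2"
    return "S3"


# Default truths per rate.  Calcification is hypo-allometric with
# ln(alpha) = -6.126 on the mg h^-1 scale (a 100 cm^2 colony calcifies
# ~0.13 mg CaCO3 h^-1, i.e. ~3 mg day^-1 -- small enough that a 3-h
# chamber incubation draws down tens of umol/kg alkalinity, not all of
# it); the package's internal mass unit is grams, hence the -ln(1000)
# shift.  Respiration and photosynthesis are near-isometric in
# mg O2 h^-1.
DEFAULT_TRUTHS = {
    "calcification": TruthParams(ln_alpha=-6.126 - math.log(1000.0), beta=0.881, sigma=0.3,
                                 sigma_zeta=(0.613, 0.075), rho=-0.58, seed=11),
    "respiration": TruthParams(ln_alpha=-4.154, beta=1.074, sigma=0.45,
                               sigma_zeta=(0.5, 0.1), rho=-0.6, seed=12),
    "net_photosynthesis": TruthParams(ln_alpha=-3.971, beta=1.033, sigma=0.45,
                                      sigma_zeta=(0.5, 0.1), rho=-0.5, seed=13),
}


def gen_study(
    truths: dict[str, TruthParams] | None = None,
    n_per_species: int = 12,
    area_range_cm2: tuple[float, float] = (10.0, 2000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """One colony table carrying true values of all three rates.

    Shares a single set of colonies (species, areas) across the rates,
    as in a real incubation campaign where each colony yields all three
    measurements.  Columns ``true_<rate>`` are whole-colony rates:
    calcification in g CaCO3 h^-1, respiration and net photosynthesis
    in mg O2 h^-1 (both positive magnitudes).
    """
    truths = dict(DEFAULT_TRUTHS) if truths is None else truths
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(truths) + 1)
    base = None
    for k, (rate, truth) in enumerate(truths.items()):
        if base is None:
            # Areas/species come from the first rate's table; later rate
            # columns are re-evaluated on those same areas below.
            tbl = gen_colonies(truth, n_per_species, area_range_cm2,
                               seed=int(child_seeds[k]), rate_name=rate)
            base = tbl.drop(columns=["zeta_intercept", "zeta_slope"])
        else:
            dev = gen_species_deviations(truth, np.random.default_rng(int(child_seeds[k])))
            dev = dev.set_index("species")
            ln_area = np.log(base["surface_area_3d_cm2"].to_numpy())
            z1 = dev.loc[base["species"], "zeta_intercept"].to_numpy()
            z2 = dev.loc[base["species"], "zeta_slope"].to_numpy()
            mu_ln = (truth.ln_alpha + z1) + (truth.beta + z2) * ln_area
            rng = np.random.default_rng(int(child_seeds[k]) + 1)
            true_ln = mu_ln + truth.sigma * rng.standard_normal(len(base))
            base[f"mu_log_{rate}"] = mu_ln
            base[f"true_log_{rate}"] = true_ln
            base[f"true_{rate}"] = np.exp(true_ln)
    return base


def gen_respirometry_trace(
    colony: pd.Series | dict,
    phase: str,
    duration_h: float = 1.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    sampling_interval_min: float = 1.0,
    stabilization_min: float = 30.0,
    drift_amplitude: float = 0.5,
    o2_start_mg_l: float = 7.0,
    temperature_c: float = 28.5,
    set_id: int = 0,
    is_control: bool = False,
) -> pd.DataFrame:
    """Simulate one O2 trace for a colony and phase.

    Concentration is linear in time with slope = flux / chamber volume
    (positive in light where net photosynthesis dominates, negative in
    dark where only respiration runs), plus a decaying stabilization
    transient over the first ``stabilization_min`` minutes and i.i.d.
    Gaussian sensor noise.  The transient is exactly zero at and after
    the stabilization boundary, so trimming recovers the pure line.
    """
    if phase not in ("light", "dark"):
        raise ValueError(f"phase must be 'light' or 'dark', got {phase!r}")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    get = colony.get if hasattr(colony, "get") else colony.__getitem__
    size_class = get("size_class", "S2") if hasattr(colony, "get") else colony["size_class"]
    volume = CHAMBER_VOLUME_L[size_class]
    if is_control:
        flux = 0.0
    elif phase == "light":
        flux = float(get("true_net_photosynthesis"))
    else:
        flux = -float(get("true_respiration"))
    slope = flux / volume  # mg L^-1 h^-1
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-12, sampling_interval_min / 60.0)
    t_stab = stabilization_min / 60.0
    drift = drift_amplitude * np.clip(1.0 - t / t_stab, 0.0, None) ** 2
    o2 = o2_start_mg_l + slope * t + drift + noise_sd * rng.standard_normal(t.size)
    return pd.DataFrame(
        {
            "colony_id": get("colony_id") if not is_control else f"CTRL_{set_id}_{seed}",
            "set_id": set_id,
            "phase": phase,
            "time_h": t,
            "o2_mg_l": o2,
            "chamber_volume_l": volume,
            "temperature_c": temperature_c,
            "is_control": is_control,
        }
    )


def gen_incubation_chemistry(
    colony: pd.Series | dict,
    duration_h: float = 3.0,
    at_start_umol_kg: float = 2300.0,
    seed: int = 0,
    noise_sd_umol_kg: float = 0.0,
    set_id: int = 0,
    is_control: bool = False,
) -> pd.DataFrame:
    """Start/end alkalinity pair encoding the colony's calcification.

    The end alkalinity is set so that the alkalinity-anomaly formula
    applied to the pair (against a zero-drop control) returns the
    colony's true whole-colony calcification rate exactly; optional
    titration noise is added on top.  Raises if the implied end
    alkalinity is non-positive (unphysically large drop).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    get = colony.get if hasattr(colony, "get") else colony.__getitem__
    size_class = get("size_class", "S2")
    volume = CHAMBER_VOLUME_L[size_class]
    rate_g_h = 0.0 if is_control else float(get("true_calcification"))
    # Invert: rate [g/h] -> mol/h -> alkalinity drop over duration.
    mol_h = rate_g_h / MOLAR_MASS_CACO3
    drop_umol_kg = mol_h * 1e6 * 2.0 * duration_h / (RHO_SW_KG_L * volume)
    at_end = at_start_umol_kg - drop_umol_kg
    if at_end <= 0:
        raise ValueError(
            f"implied end alkalinity {at_end:.1f} umol/kg is non-positive (unphysical)"
        )
    if noise_sd_umol_kg:
        rng = np.random.default_rng(seed)
        at_end += noise_sd_umol_kg * rng.standard_normal()
    return pd.DataFrame(
        [
            {
                "colony_id": get("colony_id") if not is_control else f"CTRL_{set_id}_{seed}",
                "set_id": set_id,
                "at_start_umol_kg": at_start_umol_kg,
                "at_end_umol_kg": at_end,
                "delta_t_h": duration_h,
                "chamber_volume_l": volume,
                "is_control": is_control,
            }
        ]
    )


def gen_cover_series(cfg: ScenarioConfig) -> pd.DataFrame:
    """Genus-level yearly % cover across a disturbance-recovery cycle.

    Total cover declines log-linearly from ``cover_start_pct`` to
    ``cover_min_pct`` at the disturbance year, recovers log-linearly to
    the start level by ``recovery_year`` and stays flat after.  The
    total is split among the six genera with seeded Dirichlet weights
    jittered per year, so genus trajectories wiggle while the total
    follows the prescribed path exactly.
    """
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    lo = max(cfg.cover_min_pct, 1e-9)
    hi = max(cfg.cover_start_pct, lo)
    log_lo, log_hi = math.log(lo), math.log(hi)
    total = np.empty(years.size)
    for i, y in enumerate(years):
        if y <= cfg.disturbance_year:
            f = (y - cfg.year_start) / max(1, cfg.disturbance_year - cfg.year_start)
            total[i] = math.exp(log_hi + f * (log_lo - log_hi))
        elif y <= cfg.recovery_year:
            f = (y - cfg.disturbance_year) / max(1, cfg.recovery_year - cfg.disturbance_year)
            total[i] = math.exp(log_lo + f * (log_hi - log_lo))
        else:
            total[i] = hi
    if cfg.cover_start_pct == cfg.cover_min_pct:
        total[:] = cfg.cover_start_pct
    rng = np.random.default_rng(cfg.seed)
    base_w = np.array([0.30, 0.08, 0.12, 0.08, 0.22, 0.20])  # rough genus mix
    rows = []
    for i, y in enumerate(years):
        w = rng.dirichlet(base_w * 60.0)
        for g, genus in enumerate(GENERA):
            rows.append({"year": int(y), "taxon": genus, "percent_cover": total[i] * w[g]})
    return pd.DataFrame(rows)


def gen_size_distribution(cfg: ScenarioConfig, n_draws: int = 5000) -> pd.DataFrame:
    """Shared lognormal pool of colony planar areas (cm²), all genera."""
    mu, sd = cfg.size_dist_params
    rng = np.random.default_rng(cfg.seed + 1)
    areas = np.exp(mu + sd * rng.standard_normal(n_draws))
    return pd.DataFrame({"planar_area_cm2": areas})


def _study_tables(
    truths: dict[str, TruthParams] | None,
    n_per_species: int,
    seed: int,
    trace_noise_sd: float = 0.05,
    titration_noise_sd: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build metadata, trace and chemistry tables for a full study."""
    colonies = gen_study(truths, n_per_species=n_per_species, seed=seed)
    ss = np.random.SeedSequence(seed + 1)
    seeds = iter(ss.generate_state(8 * len(colonies) + 64).tolist())
    traces, chems = [], []
    set_size = 12
    for i, (_, col) in enumerate(colonies.iterrows()):
        set_id = i // set_size
        for phase, dur in (("light", 3.0), ("dark", 1.0)):
            traces.append(
                gen_respirometry_trace(col, phase, duration_h=dur + 0.5,
                                       noise_sd=trace_noise_sd, seed=next(seeds) % 2**31,
                                       set_id=set_id)
            )
        chems.append(
            gen_incubation_chemistry(col, duration_h=3.0, seed=next(seeds) % 2**31,
                                     noise_sd_umol_kg=titration_noise_sd, set_id=set_id)
        )
    # One control per set and phase plus one control chemistry pair.
    n_sets = (len(colonies) + set_size - 1) // set_size
    control_col = {"colony_id": "", "size_class": "S2"}
    for s in range(n_sets):
        for phase, dur in (("light", 3.0), ("dark", 1.0)):
            traces.append(
                gen_respirometry_trace(control_col, phase, duration_h=dur + 0.5,
                                       noise_sd=trace_noise_sd, seed=next(seeds) % 2**31,
                                       set_id=s, is_control=True)
            )
        chems.append(
            gen_incubation_chemistry(control_col, duration_h=3.0, seed=next(seeds) % 2**31,
                                     noise_sd_umol_kg=titration_noise_sd, set_id=s,
                                     is_control=True)
        )
    meta_cols = ["colony_id", "species", "size_class", "surface_area_3d_cm2"]
    truth_cols = [c for c in colonies.columns if c.startswith(("true_", "mu_log_"))]
    metadata = colonies[meta_cols + truth_cols]
    return metadata, pd.concat(traces, ignore_index=True), pd.concat(chems, ignore_index=True)


def write_inputs(
    outdir: str | Path,
    truths: dict[str, TruthParams] | None = None,
    scenario: ScenarioConfig | None = None,
    n_per_species: int = 12,
    seed: int = 0,
    trace_noise_sd: float = 0.05,
    titration_noise_sd: float = 2.0,
) -> dict[str, Path]:
    """Write the five input CSVs and a truth manifest to ``outdir``.

    Tables: colony metadata (with ground-truth rates for recovery
    tests), respirometry traces, incubation chemistry, cover series and
    the size-distribution pool.  The manifest records every truth
    parameter and seed used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = dict(DEFAULT_TRUTHS) if truths is None else truths
    scenario = ScenarioConfig(seed=seed) if scenario is None else scenario
    metadata, traces, chems = _study_tables(
        truths, n_per_species, seed, trace_noise_sd, titration_noise_sd
    )
    cover = gen_cover_series(scenario)
    sizes = gen_size_distribution(scenario)
    paths = {
        "colonies": outdir / "colonies.csv",
        "traces": outdir / "respirometry_traces.csv",
        "chemistry": outdir / "incubation_chemistry.csv",
        "cover": outdir / "cover_series.csv",
        "sizes": outdir / "size_distribution.csv",
    }
    metadata.to_csv(paths["colonies"], index=False)
    traces.to_csv(paths["traces"], index=False)
    chems.to_csv(paths["chemistry"], index=False)
    cover.to_csv(paths["cover"], index=False)
    sizes.to_csv(paths["sizes"], index=False)
    manifest = {
        "seed": seed,
        "n_per_species": n_per_species,
        "trace_noise_sd": trace_noise_sd,
        "titration_noise_sd": titration_noise_sd,
        "truths": {k: asdict(v) for k, v in truths.items()},
        "scenario": asdict(scenario),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
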