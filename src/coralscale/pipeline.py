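"""End-to-end orchestration: simulate → process → fit → upscale → report.

Ties the stages together behind one reproducible configuration: a
single seed fans out (via ``numpy.random.SeedSequence``) to every
stochastic stage, outputs carry a metadata block (config hash, seeds,
package version), and each stage reads only the previous stage's CSV
artifacts, so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community, physio, scaling, synthdata

__all__ = ["RunConfig", "validate_inputs", "run_pipeline", "STAGES"]

log = logging.getLogger("coralscale")

STAGES = ("simulate", "process", "fit", "upscale", "report")


@dataclass
class RunConfig:
    """One reproducible run: paths, profile, constants and model settings.

    ``profile`` selects the MCMC size: ``"paper"`` is 3 chains x 5000
    draws with 2500 warm-up (7500 retained); ``"test"`` is 3 x 1000/500
    (1500 retained) for quick runs.  All other knobs default to the
    constants documented in their owning modules.
    """

    outdir: Path = Path("coralscale_run")
    seed: int = 0
    profile: str = "test"
    n_per_species: int = 12
    trace_noise_sd: float = 0.05
    titration_noise_sd: float = 2.0
    reps: int = 50
    use_posterior_draws: bool = False
    constants: physio.PhysioConstants = field(default_factory=physio.PhysioConstants)
    priors: scaling.PriorSpec = field(default_factory=scaling.PriorSpec)
    scenario: synthdata.ScenarioConfig = field(default_factory=synthdata.ScenarioConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.profile not in ("test", "paper"):
            raise ValueError(f"profile must be 'test' or 'paper', got {self.profile!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file (flat keys matching the field names)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        nested = {}
        if "constants" in raw:
            nested["constants"] = physio.PhysioConstants(**raw.pop("constants"))
        if "priors" in raw:
            nested["priors"] = scaling.PriorSpec(**raw.pop("priors"))
        if "scenario" in raw:
            sc = raw.pop("scenario")
            if "size_dist_params" in sc:
                sc["size_dist_params"] = tuple(sc["size_dist_params"])
            nested["scenario"] = synthdata.ScenarioConfig(**sc)
        return cls(**raw, **nested)

    def fit_config(self, seed: int) -> scaling.FitConfig:
        base = scaling.PAPER_FIT if self.profile == "paper" else scaling.TEST_FIT
        return dataclasses.replace(base, seed=seed)

    def digest(self) -> str:
        """Short stable hash of the whole configuration."""
        enc = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (Path, np.floating, np.integer)):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema and invariant checks on parsed input tables.

    Returns a violation table (columns: table, row, severity, message);
    ``severity == "hard"`` rows should abort a run.  Checked: required
    columns, positive areas/volumes/durations, monotone trace times per
    colony and phase, cover percentages in [0, 100], positive planar
    areas.
    """
    issues: list[dict] = []

    def hard(table, row, msg):
        issues.append({"table": table, "row": row, "severity": "hard", "message": msg})

    def soft(table, row, msg):
        issues.append({"table": table, "row": row, "severity": "soft", "message": msg})

    required = {
        "colonies": ["colony_id", "species", "size_class", "surface_area_3d_cm2"],
        "traces": ["colony_id", "set_id", "phase", "time_h", "o2_mg_l",
                   "chamber_volume_l", "temperature_c", "is_control"],
        "chemistry": ["colony_id", "set_id", "at_start_umol_kg", "at_end_umol_kg",
                      "delta_t_h", "chamber_volume_l", "is_control"],
        "cover": ["year", "taxon", "percent_cover"],
        "sizes": ["planar_area_cm2"],
    }
    for name, cols in required.items():
        if name not in tables:
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            hard(name, -1, f"missing required columns: {missing}")

    if "colonies" in tables and "surface_area_3d_cm2" in tables["colonies"]:
        bad = tables["colonies"]["surface_area_3d_cm2"] <= 0
        for i in tables["colonies"].index[bad]:
            hard("colonies", int(i), "non-positive 3D surface area")

    if "traces" in tables and {"colony_id", "phase", "time_h"} <= set(tables["traces"].columns):
        for (cid, phase), grp in tables["traces"].groupby(["colony_id", "phase"]):
            t = grp["time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                hard("traces", int(grp.index[0]), f"non-monotone times for {cid}/{phase}")
            if len(grp) < 3:
                soft("traces", int(grp.index[0]), f"fewer than 3 points for {cid}/{phase}")

    if "chemistry" in tables:
        chem = tables["chemistry"]
        for col in ("at_start_umol_kg", "at_end_umol_kg", "delta_t_h", "chamber_volume_l"):
            if col in chem.columns:
                bad = chem[col] <= 0
                for i in chem.index[bad]:
                    hard("chemistry", int(i), f"non-positive {col}")

    if "cover" in tables and "percent_cover" in tables["cover"].columns:
        bad = ~tables["cover"]["percent_cover"].between(0, 100)
        for i in tables["cover"].index[bad]:
            hard("cover", int(i), "percent cover outside [0, 100]")

    if "sizes" in tables and "planar_area_cm2" in tables["sizes"].columns:
        bad = tables["sizes"]["planar_area_cm2"] <= 0
        for i in tables["sizes"].index[bad]:
            hard("sizes", int(i), "non-positive planar area")

    return pd.DataFrame(issues, columns=["table", "row", "severity", "message"])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

_INPUT_FILES = {
    "colonies": "colonies.csv",
    "traces": "respirometry_traces.csv",
    "chemistry": "incubation_chemistry.csv",
    "cover": "cover_series.csv",
    "sizes": "size_distribution.csv",
}

RATE_COLUMNS = {
    "calcification": "calcification_g_h",
    "respiration": "respiration_mg_h",
    "net_photosynthesis": "net_photo_mg_h",
}


def _read_inputs(outdir: Path) -> dict[str, pd.DataFrame]:
    tables = {}
    for key, fname in _INPUT_FILES.items():
        path = outdir / fname
        if not path.exists():
            raise FileNotFoundError(
                f"required upstream artifact missing: {path} (run the 'simulate' "
                "stage or point outdir at existing inputs)"
            )
        tables[key] = pd.read_csv(path)
    return tables


def _stage_simulate(cfg: RunConfig, seeds: dict[str, int]) -> dict[str, Path]:
    scenario = dataclasses.replace(cfg.scenario, seed=seeds["simulate"])
    paths = synthdata.write_inputs(
        cfg.outdir,
        scenario=scenario,
        n_per_species=cfg.n_per_species,
        seed=seeds["simulate"],
        trace_noise_sd=cfg.trace_noise_sd,
        titration_noise_sd=cfg.titration_noise_sd,
    )
    log.info("simulate: wrote %d input tables to %s", len(paths) - 1, cfg.outdir)
    return paths


def _stage_process(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    tables = _read_inputs(cfg.outdir)
    report = validate_inputs(tables)
    hard = report[report["severity"] == "hard"]
    if len(hard):
        raise ValueError(f"input validation failed:\n{hard.to_string(index=False)}")
    retained, rejections = physio.process_study(
        tables["colonies"], tables["traces"], tables["chemistry"], cfg.constants
    )
    retained.to_csv(cfg.outdir / "retained_colonies.csv", index=False)
    rejections.to_csv(cfg.outdir / "qc_rejections.csv", index=False)
    log.info(
        "process: %d colonies retained, %d rejections (%s)",
        len(retained), len(rejections),
        ", ".join(f"{r}={c}" for r, c in rejections["rule"].value_counts().items()) or "none",
    )
    return retained, rejections


def _stage_fit(cfg: RunConfig, seeds: dict[str, int]) -> dict[str, scaling.PosteriorDraws]:
    retained = pd.read_csv(cfg.outdir / "retained_colonies.csv")
    fits = {}
    for i, (rate, col) in enumerate(RATE_COLUMNS.items()):
        fit_cfg = cfg.fit_config(seeds["fit"] + i)
        draws = scaling.fit_scaling_model(retained, col, cfg.priors, fit_cfg)
        fits[rate] = draws
        summary = scaling.summarize_posterior(draws)
        summary.insert(0, "rate", rate)
        summary.to_csv(cfg.outdir / f"posterior_summary_{rate}.csv", index=False)
        _draws_frame(draws).to_csv(cfg.outdir / f"posterior_draws_{rate}.csv", index=False)
        log.info(
            "fit[%s]: %d retained draws, max R-hat %.3f, converged=%s",
            rate, draws.n_retained, max(draws.rhat_values.values()), draws.converged,
        )
    fixed = pd.concat(
        [pd.read_csv(cfg.outdir / f"posterior_summary_{r}.csv") for r in RATE_COLUMNS]
    )
    fixed[fixed["kind"] != "species"].to_csv(cfg.outdir / "table_fixed_effects.csv", index=False)
    fixed[fixed["kind"] == "species"].to_csv(cfg.outdir / "table_species.csv", index=False)
    return fits


def _draws_frame(draws: scaling.PosteriorDraws) -> pd.DataFrame:
    c, t = draws.ln_alpha.shape
    out = {
        "chain": np.repeat(np.arange(c), t),
        "draw": np.tile(np.arange(t), c),
        "ln_alpha": draws.flat(draws.ln_alpha),
        "beta": draws.flat(draws.beta),
        "sigma": draws.flat(draws.sigma),
        "sigma_zeta_intercept": draws.flat(draws.sigma_zeta[..., 0]),
        "sigma_zeta_slope": draws.flat(draws.sigma_zeta[..., 1]),
        "rho": draws.flat(draws.rho),
    }
    for j, sp in enumerate(draws.species):
        key = sp.split()[0].lower()
        out[f"intercept_{key}"] = draws.flat(draws.species_intercept)[:, j]
        out[f"slope_{key}"] = draws.flat(draws.species_slope)[:, j]
    return pd.DataFrame(out)


def _coefficients_from_fits(
    fits: dict[str, scaling.PosteriorDraws], use_draws: bool
) -> dict[str, community.TaxonCoefficients]:
    p = fits["net_photosynthesis"]
    g = fits["calcification"]
    coeffs = {}
    for j, sp in enumerate(p.species):
        jg = g.species.index(sp)
        if use_draws:
            ap = np.exp(p.flat(p.species_intercept)[:, j])
            bp = p.flat(p.species_slope)[:, j]
            ag = np.exp(g.flat(g.species_intercept)[:, jg])
            bg = g.flat(g.species_slope)[:, jg]
        else:
            ap = float(np.exp(p.flat(p.species_intercept)[:, j]).mean())
            bp = float(p.flat(p.species_slope)[:, j].mean())
            ag = float(np.exp(g.flat(g.species_intercept)[:, jg]).mean())
            bg = float(g.flat(g.species_slope)[:, jg].mean())
        # Calcification was fitted in g h^-1; bring it to mg h^-1.
        coeffs[sp] = community.TaxonCoefficients(ap, bp, ag, bg, calc_to_mg=1000.0)
    return coeffs


def _stage_upscale(
    cfg: RunConfig, fits: dict[str, scaling.PosteriorDraws], seeds: dict[str, int]
) -> pd.DataFrame:
    cover = pd.read_csv(cfg.outdir / "cover_series.csv")
    sizes = pd.read_csv(cfg.outdir / "size_distribution.csv")["planar_area_cm2"]
    coeffs = _coefficients_from_fits(fits, cfg.use_posterior_draws)
    series = community.ratio_timeseries(
        cover, sizes, coeffs, reps=cfg.reps, seed=seeds["upscale"]
    )
    series.to_csv(cfg.outdir / "ratio_timeseries.csv", index=False)
    community.species_ratio_table(coeffs).to_csv(
        cfg.outdir / "species_ratio_table.csv", index=False
    )
    log.info("upscale: %d years, %d replicates each", len(series), cfg.reps)
    return series


def _stage_report(cfg: RunConfig, seeds: dict[str, int]) -> None:
    meta = {
        "package_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "profile": cfg.profile,
        "config": _as_jsonable(cfg),
        "outputs": sorted(p.name for p in cfg.outdir.glob("*.csv")),
    }
    (cfg.outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    log.info("report: metadata written (config %s)", meta["config_digest"])


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order.

    Stage seeds derive deterministically from ``cfg.seed``, so a rerun
    with the same config is identical for the deterministic stages.
    Returns a dict of in-memory artifacts keyed by stage name.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    state = np.random.SeedSequence(cfg.seed).generate_state(len(STAGES))
    seeds = {name: int(s % 2 ** 31) for name, s in zip(STAGES, state)}
    artifacts: dict = {}
    if "simulate" in stages:
        artifacts["simulate"] = _stage_simulate(cfg, seeds)
    if "process" in stages:
        artifacts["process"] = _stage_process(cfg)
    if "fit" in stages:
        artifacts["fit"] = _stage_fit(cfg, seeds)
    if "upscale" in stages:
        if "fit" not in artifacts:
            raise ValueError(
                "stage dependency missing: 'upscale' needs the in-memory posterior "
                "draws from 'fit'; request both (e.g. stages=('fit', 'upscale'))"
            )
        artifacts["upscale"] = _stage_upscale(cfg, artifacts["fit"], seeds)
    if "report" in stages:
        _stage_report(cfg, seeds)
    return artifacts
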