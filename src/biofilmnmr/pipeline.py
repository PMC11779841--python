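"""Configuration, orchestration and report generation.

A single structured YAML config drives reproducible end-to-end runs:
``run_simulate`` writes a complete synthetic dataset, ``run_analyze``
executes quantification → kinetics → dynamics → clustering over a
dataset directory and writes every figure-analog table as CSV, and
``run_recovery_suite`` compares every estimate against the dataset's
ground truth with documented tolerances.

All stages communicate only through the documented file schemas; each
run emits the resolved configuration verbatim plus a JSON report with
per-stage outputs, aggregated warnings, seeds and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering as clus
from . import dynamics as dyn
from . import kinetics as kin
from . import quant
from . import synthetic as synth
from .errors import BiofilmNMRError, ConfigurationError, InputError
from .spectra import Spectrum1D

logger = logging.getLogger(__name__)

#: Name of the shipped preset carrying all the 5-day defaults.
PRESET_NAME = "bsubtilis-5day"

#: Recovery-suite tolerances (documented in the methods note).  The
#: mobile-fraction budget covers both the short-recycle saturation bias
#: (up to ~0.015 for a 0.5 s / 20 s T1 split) and Lorentzian tail leakage
#: between component windows, which peaks when the lipid spike rivals the
#: protein biomass.
RECOVERY_TOLERANCES = {
    "relative_density_abs": 0.05,
    "mobile_fraction_abs": 0.05,
    "t1_rel": 0.05,
    "order_parameter_abs": 0.02,
    "cluster_ari_min": 1.0,
    "proportion_abs": 1.0,  # percentage points
}


@dataclass
class RunConfig:
    """Resolved run configuration (see :func:`load_config`)."""

    output_dir: Path
    dataset_dir: Path | None = None
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    regions: dict[str, list[tuple[float, float]]] | None = None
    reference_day: int = 2
    kinetics_intervals: tuple[int, int] = (3, 4)
    protein_category: str = "proteins"
    carbohydrate_category: str = "exopolysaccharides"
    rigid_limit_khz: float = dyn.RIGID_LIMIT_CH_KHZ
    fslg_scaling: float = dyn.FSLG_SCALING
    powder_step_deg: float | None = None
    cluster_days: tuple[int, ...] = clus.DEFAULT_DAYS
    k_range: tuple[int, ...] = clus.DEFAULT_K_RANGE
    force_k: int | None = None
    kmeans_restarts: int = 50
    ratio_table: Path | None = None

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, Path):
                out[k] = str(v)
        out["dataset_dir"] = None if self.dataset_dir is None else str(self.dataset_dir)
        out["ratio_table"] = None if self.ratio_table is None else str(self.ratio_table)
        return out


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(source: str | Path | dict, output_dir: str | Path | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``source`` is a YAML file path, a dict, or the preset name
    ``"bsubtilis-5day"`` (all paper-era defaults).  Unknown keys raise a
    :class:`ConfigurationError` naming the key.
    """
    if isinstance(source, dict):
        raw = dict(source)
    elif str(source) == PRESET_NAME:
        raw = {}
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if output_dir is not None:
        raw["output_dir"] = output_dir
    if "output_dir" not in raw:
        raise ConfigurationError("missing config key 'output_dir'")
    raw["output_dir"] = Path(raw["output_dir"])
    for key in ("dataset_dir", "ratio_table"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    for key in ("kinetics_intervals", "cluster_days", "k_range"):
        if key in raw:
            raw[key] = tuple(int(v) for v in raw[key])
    cfg = RunConfig(**raw)
    if cfg.regions is not None:
        quant.RegionSet({k: [tuple(iv) for iv in v] for k, v in cfg.regions.items()})
    return cfg


@dataclass
class RunReport:
    """Per-stage outputs, warnings and provenance of one run."""

    version: str
    seed: int
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    input_checksums: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self) -> str:
        def conv(obj):
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return json.dumps(conv(dataclasses.asdict(self)), indent=1, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_spectra(dataset_dir: Path) -> list[Spectrum1D]:
    files = sorted((dataset_dir / "spectra").glob("*.tsv"))
    if not files:
        raise InputError(f"no spectra found under {dataset_dir / 'spectra'}")
    return [Spectrum1D.read(f) for f in files]


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Build the scenario and write the full synthetic dataset."""
    outdir = config.output_dir
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
    dataset_dir = outdir / "dataset"
    dataset_dir.mkdir(parents=True, exist_ok=True)
    scenario = synth.build_scenario(config.scenario, seed=config.seed)
    paths = synth.write_dataset(scenario, dataset_dir)
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(config.resolved()))
    return paths


def _stage_quantify(config: RunConfig, dataset_dir: Path, outdir: Path) -> dict:
    spectra = _load_spectra(dataset_dir)
    dp = [s for s in spectra if s.mode in ("qDP", "DP2s")]
    regions = quant.RegionSet(
        {k: [tuple(iv) for iv in v] for k, v in config.regions.items()}
    ) if config.regions else quant.RegionSet()
    total = quant.total_biomass_series(dp, reference_day=config.reference_day)
    comp = quant.component_quant(dp, regions, reference_day=config.reference_day)
    total_path = outdir / "total_biomass.csv"
    comp_path = outdir / "component_biomass.csv"
    total.to_csv(total_path, index=False, float_format="%.8g")
    comp.to_csv(comp_path, index=False, float_format="%.8g")

    volumes = pd.read_csv(dataset_dir / "peak_volumes.csv")
    category_map = json.loads((dataset_dir / "category_map.json").read_text())
    table = quant.group_components(
        volumes, category_map, reference=(config.protein_category, config.reference_day)
    )
    table_path = outdir / "component_table.csv"
    table.to_csv(table_path, index=False, float_format="%.8g")
    return {
        "total_biomass": total_path,
        "component_biomass": comp_path,
        "component_table": table_path,
    }


def _stage_kinetics(config: RunConfig, outdir: Path) -> dict:
    table = pd.read_csv(outdir / "component_table.csv")
    dp1, dp2, dc1, dc2 = quant.degradation_observations(
        table,
        protein_category=config.protein_category,
        carbohydrate_category=config.carbohydrate_category,
        intervals=config.kinetics_intervals,
    )
    sol = kin.solve_proportions(dp1, dp2, dc1, dc2)
    i1, i2 = config.kinetics_intervals
    frame = pd.DataFrame(
        [
            {
                "interval_1": f"day {i1}", "interval_2": f"day {i2}",
                "dp1": dp1, "dp2": dp2, "dc1": dc1, "dc2": dc2,
                "p1_percent": sol.p1, "p2_percent": sol.p2,
                "c1_percent": sol.c1, "c2_percent": sol.c2,
            }
        ]
    )
    sol_path = outdir / "degraded_matrix_proportions.csv"
    frame.to_csv(sol_path, index=False, float_format="%.8g")
    report_path = outdir / "degraded_matrix_report.txt"
    p1, p2, c1, c2 = sol.rounded()
    report_path.write_text(
        "Degraded-matrix composition (first-order kinetics, equal volume and "
        "total biomass assumed):\n"
        f"  interval ending day {i1}: proteins {p1}%, carbohydrates {c1}%\n"
        f"  interval ending day {i2}: proteins {p2}%, carbohydrates {c2}%\n"
        f"  degraded quantities used: proteins {dp1:.4g}/{dp2:.4g}, "
        f"carbohydrates {dc1:.4g}/{dc2:.4g}\n"
    )
    return {"proportions": sol_path, "report": report_path}


def _stage_relax(config: RunConfig, dataset_dir: Path, outdir: Path) -> dict:
    ir = pd.read_csv(dataset_dir / "inversion_recovery.csv")
    t1_rows = []
    for site, grp in ir.groupby("site", sort=True):
        series = dyn.InversionRecoverySeries(
            site=site,
            delays=grp["delay_s"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            noise_sigma=float(grp["sigma"].iloc[0]),
        )
        fit = dyn.fit_t1(series)
        t1_rows.append(
            {"site": site, "t1_s": fit.t1, "offset": fit.a, "scale": fit.b,
             "residual_norm": fit.residual_norm}
        )
    t1_path = outdir / "t1_fits.csv"
    pd.DataFrame(t1_rows).to_csv(t1_path, index=False, float_format="%.8g")

    ds = pd.read_csv(dataset_dir / "dipshift.csv")
    op_rows = []
    for site, grp in ds.groupby("site", sort=True):
        curve = dyn.DipshiftCurve(
            site=site,
            t1_frac=grp["t1_frac"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            multiplicity=str(grp["multiplicity"].iloc[0]),
            mas_rate_khz=float(grp["mas_rate_khz"].iloc[0]),
        )
        fit = dyn.fit_order_parameter(
            curve,
            rigid_limit_khz=config.rigid_limit_khz,
            scaling=config.fslg_scaling,
            powder_step_deg=config.powder_step_deg,
        )
        op_rows.append(
            {
                "site": site,
                "multiplicity": curve.multiplicity,
                "coupling_khz": fit.coupling_khz,
                "order_parameter": fit.order_parameter,
                "residual_norm": fit.residual_norm,
            }
        )
    op_path = outdir / "order_parameters.csv"
    pd.DataFrame(op_rows).to_csv(op_path, index=False, float_format="%.8g")
    return {"t1_fits": t1_path, "order_parameters": op_path}


def _stage_cluster(config: RunConfig, dataset_dir: Path, outdir: Path) -> dict:
    bio = pd.read_csv(dataset_dir / "sugar_biofilm.csv")
    med = pd.read_csv(dataset_dir / "sugar_medium.csv")
    result = clus.cluster_sugars(
        bio,
        med,
        days=config.cluster_days,
        k_range=config.k_range,
        seed=config.seed,
        n_init=config.kmeans_restarts,
        force_k=config.force_k,
    )
    scores_path = outdir / "pca_scores.csv"
    result.scores.assign(cluster=result.labels).to_csv(scores_path, float_format="%.8g")
    loadings_path = outdir / "pca_loadings.csv"
    result.loadings.to_csv(loadings_path, float_format="%.8g")
    summary_path = outdir / "cluster_summary.json"
    summary = {
        "k": result.k,
        "explained_variance_ratio": result.explained_variance_ratio.tolist(),
        "explained_variance_pct_2d": float(100.0 * result.explained_variance_ratio.sum()),
        "silhouette_by_k": {str(k): v for k, v in result.silhouette_by_k.items()},
        "labels": result.labels.to_dict(),
        "dropped": result.dropped,
        "seed": result.seed,
    }
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return {"scores": scores_path, "loadings": loadings_path, "summary": summary_path}


def _stage_ratio_table_pca(config: RunConfig, outdir: Path) -> dict:
    """Optional: 2-component PCA variance of a user-supplied per-sugar ratio
    table (rows = sugars, columns = days).  Reported as unavailable when no
    table is configured."""
    if config.ratio_table is None:
        return {"status": "unavailable", "reason": "no ratio table supplied"}
    feats = pd.read_csv(config.ratio_table, index_col=0)
    pct = clus.pca_variance_from_ratio_table(feats)
    out = outdir / "ratio_table_pca.json"
    out.write_text(json.dumps({"explained_variance_pct_2d": pct}, indent=1) + "\n")
    return {"status": "ok", "explained_variance_pct_2d": pct, "path": out}


def run_analyze(config: RunConfig) -> RunReport:
    """Run every analysis stage over a dataset directory.

    Stage failures are recorded in the report (``failed_stage``/``error``)
    with partial results preserved; callers decide the exit code.
    """
    dataset_dir = config.dataset_dir or (config.output_dir / "dataset")
    outdir = config.output_dir / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed, config=config.resolved())
    for f in sorted(dataset_dir.rglob("*")):
        if f.is_file() and f.suffix in (".csv", ".tsv", ".json"):
            report.input_checksums[str(f.relative_to(dataset_dir))] = _sha256(f)

    stages = [
        ("quantify", lambda: _stage_quantify(config, dataset_dir, outdir)),
        ("kinetics", lambda: _stage_kinetics(config, outdir)),
        ("relax", lambda: _stage_relax(config, dataset_dir, outdir)),
        ("cluster", lambda: _stage_cluster(config, dataset_dir, outdir)),
        ("ratio_table_pca", lambda: _stage_ratio_table_pca(config, outdir)),
    ]
    for name, fn in stages:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn()
            report.warnings.extend(f"{name}: {w.message}" for w in caught)
            report.stages[name] = {
                k: (str(v) if isinstance(v, Path) else v) for k, v in result.items()
            }
        except (BiofilmNMRError, OSError, KeyError, pd.errors.ParserError) as exc:
            report.failed_stage = name
            report.error = f"{type(exc).__name__}: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            break
    (config.output_dir / "run_report.json").write_text(report.to_json())
    return report


# --------------------------------------------------------------------------
# recovery suite
# --------------------------------------------------------------------------


def run_recovery_suite(config: RunConfig) -> dict:
    """Simulate, analyze, and compare every estimate to ground truth.

    Returns a machine-readable summary: per-check pass/fail with the
    measured worst-case deviations, and an overall ``passed`` flag.
    """
    run_simulate(config)
    report = run_analyze(config)
    if report.failed_stage is not None:
        raise BiofilmNMRError(
            f"analysis stage {report.failed_stage!r} failed: {report.error}"
        )
    dataset_dir = config.dataset_dir or (config.output_dir / "dataset")
    outdir = config.output_dir / "analysis"
    truth = synth.GroundTruth.from_json((dataset_dir / "ground_truth.json").read_text())
    tol = RECOVERY_TOLERANCES
    checks: dict[str, dict] = {}

    comp = pd.read_csv(outdir / "component_biomass.csv")
    worst = 0.0
    for _, row in comp.iterrows():
        name, day = row["component"], int(row["day"])
        true_by_day = truth.biomass_by_day[name]
        ref = true_by_day[config.reference_day]
        worst = max(worst, abs(row["relative_density"] - true_by_day[day] / ref))
    checks["relative_density"] = {
        "worst_abs_error": worst, "tolerance": tol["relative_density_abs"],
        "passed": bool(worst <= tol["relative_density_abs"]),
    }

    worst = 0.0
    for _, row in comp.iterrows():
        true_mf = truth.mobile_fraction_by_day[row["component"]][int(row["day"])]
        worst = max(worst, abs(row["mobile_fraction"] - true_mf))
    checks["mobile_fraction"] = {
        "worst_abs_error": worst, "tolerance": tol["mobile_fraction_abs"],
        "passed": bool(worst <= tol["mobile_fraction_abs"]),
    }

    t1 = pd.read_csv(outdir / "t1_fits.csv")
    worst = 0.0
    for _, row in t1.iterrows():
        true_t1 = truth.t1_by_site[row["site"]]
        worst = max(worst, abs(row["t1_s"] - true_t1) / true_t1)
    checks["t1"] = {
        "worst_rel_error": worst, "tolerance": tol["t1_rel"],
        "passed": bool(worst <= tol["t1_rel"]),
    }

    op = pd.read_csv(outdir / "order_parameters.csv")
    worst = 0.0
    for _, row in op.iterrows():
        true_s = truth.order_parameter_by_site[row["site"]]["order_parameter"]
        worst = max(worst, abs(row["order_parameter"] - true_s))
    checks["order_parameter"] = {
        "worst_abs_error": worst, "tolerance": tol["order_parameter_abs"],
        "passed": bool(worst <= tol["order_parameter_abs"]),
    }

    summary = json.loads((outdir / "cluster_summary.json").read_text())
    labels = summary["labels"]
    true_labels = [truth.sugar_cluster_labels[s] for s in labels]
    from sklearn.metrics import adjusted_rand_score

    ari = float(adjusted_rand_score(true_labels, list(labels.values())))
    checks["sugar_clusters"] = {
        "ari": ari, "tolerance": tol["cluster_ari_min"],
        "passed": bool(ari >= tol["cluster_ari_min"]),
    }

    prop = pd.read_csv(outdir / "degraded_matrix_proportions.csv").iloc[0]
    cat = truth.category_quantity_by_day
    i1, i2 = config.kinetics_intervals
    true_sol = kin.solve_proportions(
        cat[config.protein_category][i1 - 1] - cat[config.protein_category][i1],
        cat[config.protein_category][i2 - 1] - cat[config.protein_category][i2],
        cat[config.carbohydrate_category][i1 - 1] - cat[config.carbohydrate_category][i1],
        cat[config.carbohydrate_category][i2 - 1] - cat[config.carbohydrate_category][i2],
    )
    worst = max(
        abs(prop["p1_percent"] - true_sol.p1), abs(prop["p2_percent"] - true_sol.p2),
        abs(prop["c1_percent"] - true_sol.c1), abs(prop["c2_percent"] - true_sol.c2),
    )
    checks["degraded_proportions"] = {
        "worst_abs_error_pct_points": worst, "tolerance": tol["proportion_abs"],
        "passed": bool(worst <= tol["proportion_abs"]),
    }

    passed = all(c["passed"] for c in checks.values())
    out = {"passed": passed, "checks": checks, "seed": config.seed}
    (config.output_dir / "recovery_summary.json").write_text(
        json.dumps(out, indent=1, sort_keys=True, default=float) + "\n"
    )
    return out
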