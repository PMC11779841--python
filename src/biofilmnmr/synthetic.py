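"""Ground-truth-annotated synthetic datasets for the whole pipeline.

The generator emulates a 5-day static biofilm time course as seen by
solid-state NMR: carbon biomass peaks on day 2 and decays to ~20% of its
maximum by day 5; a dominant mobile phase (~90% early, ~76% late) is
distinguished from a minor rigid phase by its much shorter ¹³C T1;
component classes occupy their characteristic chemical-shift regions;
monosaccharides partition between biofilm and spent medium in clustered
family patterns; and per-site T1 values (0.5–2.6 s) and order parameters
(0.49–1.0) parameterize the dynamics measurements.

Spectra are rendered as sums of Lorentzian lines (mobile-phase ssNMR
lines are near-Lorentzian).  Polarization modes weight the two dynamic
phases differently:

* qDP   — quantitative; both phases fully detected,
* DP2s  — each phase attenuated by the saturation factor
          ``1 − exp(−RD/T1)`` with the 2 s recycle delay,
* CP    — rigid phase only, scaled by a global non-quantitative
          efficiency and flagged as such.

Every emitted dataset references one :class:`GroundTruth` record holding
the true value of every quantity the pipeline later estimates.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics
from .errors import ConfigurationError, InputError
from .spectra import MODES, SHORT_RECYCLE_DELAY_S, Spectrum1D

__all__ = [
    "ComponentSpec",
    "SugarSpec",
    "ScenarioSpec",
    "GroundTruth",
    "build_scenario",
    "default_config",
    "render_spectrum",
    "emit_inversion_recovery",
    "emit_dipshift",
    "emit_sugar_tables",
    "emit_component_volumes",
    "write_dataset",
]

#: Default inversion-recovery delay grid, in units of the site's T1.
DEFAULT_IR_DELAY_FACTORS = (
    0.0, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0,
)


def _stream(seed: int, label: str, *extra: int) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from the scenario seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode()), *extra])


# --------------------------------------------------------------------------
# scenario description
# --------------------------------------------------------------------------


@dataclass
class ComponentSpec:
    """One component class: its peaks, biomass trajectory and phase split."""

    name: str
    peaks: list[tuple[float, float, float]]  # (center ppm, HWHM ppm, rel. area)
    biomass_by_day: dict[int, float]
    mobile_fraction_by_day: dict[int, float]
    t1_mobile_s: float = 0.5
    t1_rigid_s: float = 20.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ConfigurationError(f"components.{self.name}.peaks: empty")
        for c, w, a in self.peaks:
            if not w > 0:
                raise ConfigurationError(
                    f"components.{self.name}.peaks: width must be > 0 (peak at {c} ppm)"
                )
            if a < 0:
                raise ConfigurationError(
                    f"components.{self.name}.peaks: area must be >= 0 (peak at {c} ppm)"
                )
        self.biomass_by_day = {int(k): float(v) for k, v in self.biomass_by_day.items()}
        self.mobile_fraction_by_day = {
            int(k): float(v) for k, v in self.mobile_fraction_by_day.items()
        }
        for d, b in self.biomass_by_day.items():
            if b < 0:
                raise ConfigurationError(
                    f"components.{self.name}.biomass_by_day.{d}: must be >= 0, got {b}"
                )
        for d, f in self.mobile_fraction_by_day.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"components.{self.name}.mobile_fraction_by_day.{d}: "
                    f"must be in [0, 1], got {f}"
                )
        for key, t1 in (("t1_mobile_s", self.t1_mobile_s), ("t1_rigid_s", self.t1_rigid_s)):
            if not t1 > 0:
                raise ConfigurationError(f"components.{self.name}.{key}: must be > 0, got {t1}")

    def total_area(self) -> float:
        return sum(a for _, _, a in self.peaks)


@dataclass
class SugarSpec:
    """One monosaccharide: biofilm quantities and biofilm/medium partition.

    ``ratio_by_day`` maps day -> biofilm/medium integral ratio; a ``None``
    ratio means the sugar is undetected in the medium that day (emitted as
    missing, never zero).  ``family`` is the ground-truth cluster label.
    """

    name: str
    family: str
    biofilm_by_day: dict[int, float]
    ratio_by_day: dict[int, float | None]

    def __post_init__(self) -> None:
        self.biofilm_by_day = {int(k): float(v) for k, v in self.biofilm_by_day.items()}
        self.ratio_by_day = {
            int(k): (None if v is None else float(v)) for k, v in self.ratio_by_day.items()
        }
        for d, v in self.biofilm_by_day.items():
            if v < 0:
                raise ConfigurationError(
                    f"sugars.{self.name}.biofilm_by_day.{d}: must be >= 0, got {v}"
                )
        for d, r in self.ratio_by_day.items():
            if r is not None and r <= 0:
                raise ConfigurationError(
                    f"sugars.{self.name}.ratio_by_day.{d}: must be > 0 or null, got {r}"
                )


@dataclass
class ScenarioSpec:
    """A fully resolved synthetic scenario; identical (config, seed) pairs
    produce bitwise-identical scenarios and datasets."""

    days: list[int]
    components: list[ComponentSpec]
    sugars: list[SugarSpec]
    t1_sites: dict[str, float]
    dipshift_sites: dict[str, tuple[str, float]]
    mobile_categories: dict[str, dict[int, float]]
    seed: int = 0
    noise_sigma: float = 0.0
    ir_noise_sigma: float = 0.0
    dipshift_noise_sigma: float = 0.0
    sugar_noise_cv: float = 0.0
    ppm_axis: tuple[float, float, int] = (0.0, 200.0, 4096)
    mas_rate_khz: float = dynamics.DEFAULT_MAS_KHZ
    sample_mass_mg_by_day: dict[int, float] = field(default_factory=dict)
    scans_per_mode: dict[str, int] = field(
        default_factory=lambda: {"qDP": 256, "DP2s": 1024, "CP": 2048}
    )
    cp_efficiency: float = 0.4
    ir_delay_factors: tuple[float, ...] = DEFAULT_IR_DELAY_FACTORS

    def __post_init__(self) -> None:
        self.days = [int(d) for d in self.days]
        if sorted(set(self.days)) != self.days:
            raise ConfigurationError("days: must be strictly increasing")
        lo, hi, n = self.ppm_axis
        if int(n) < 2:
            raise ConfigurationError(f"ppm_axis: n points must be >= 2, got {n}")
        if not hi > lo:
            raise ConfigurationError("ppm_axis: max must exceed min")
        self.ppm_axis = (float(lo), float(hi), int(n))
        for key in ("noise_sigma", "ir_noise_sigma", "dipshift_noise_sigma", "sugar_noise_cv"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"{key}: must be >= 0, got {getattr(self, key)}")
        if not self.mas_rate_khz > 0:
            raise ConfigurationError(f"mas_rate_khz: must be > 0, got {self.mas_rate_khz}")
        if not self.sample_mass_mg_by_day:
            self.sample_mass_mg_by_day = {d: 30.0 for d in self.days}
        self.sample_mass_mg_by_day = {
            int(k): float(v) for k, v in self.sample_mass_mg_by_day.items()
        }
        for d, m in self.sample_mass_mg_by_day.items():
            if not m > 0:
                raise ConfigurationError(
                    f"sample_mass_mg_by_day.{d}: must be > 0, got {m}"
                )
        for mode, ns in self.scans_per_mode.items():
            if mode not in MODES:
                raise ConfigurationError(f"scans_per_mode.{mode}: unknown mode")
            if int(ns) < 1:
                raise ConfigurationError(f"scans_per_mode.{mode}: must be >= 1, got {ns}")
        self.scans_per_mode = {k: int(v) for k, v in self.scans_per_mode.items()}
        if not 0.0 < self.cp_efficiency <= 1.0:
            raise ConfigurationError(
                f"cp_efficiency: must be in (0, 1], got {self.cp_efficiency}"
            )
        for site, t1 in self.t1_sites.items():
            if not t1 > 0:
                raise ConfigurationError(f"t1_sites.{site}: T1 must be > 0, got {t1}")
        for site, (mult, s) in self.dipshift_sites.items():
            if mult not in dynamics.MULTIPLICITIES:
                raise ConfigurationError(
                    f"dipshift_sites.{site}: multiplicity must be CH or CH2, got {mult!r}"
                )
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(
                    f"dipshift_sites.{site}: order parameter must be in [0, 1], got {s}"
                )
        self.mobile_categories = {
            cat: {int(k): float(v) for k, v in by_day.items()}
            for cat, by_day in self.mobile_categories.items()
        }
        for cat, by_day in self.mobile_categories.items():
            for d, q in by_day.items():
                if q < 0:
                    raise ConfigurationError(
                        f"mobile_categories.{cat}.{d}: must be >= 0, got {q}"
                    )

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise InputError(f"no component named {name!r}")


# --------------------------------------------------------------------------
# defaults: the 5-day B. subtilis-like trajectory
# --------------------------------------------------------------------------


def default_config() -> dict:
    """The default scenario: biomass peaking on day 2 and decaying to 20%
    of its maximum on day 5, with a ~90% early / ~76% late mobile phase."""
    return {
        "days": [1, 2, 3, 4, 5],
        "noise_sigma": 0.0,
        "ir_noise_sigma": 0.0,
        "dipshift_noise_sigma": 0.0,
        "sugar_noise_cv": 0.0,
        "ppm_axis": (0.0, 200.0, 4096),
        "mas_rate_khz": dynamics.DEFAULT_MAS_KHZ,
        "cp_efficiency": 0.4,
        "components": {
            "carbohydrate": {
                # anomeric + ring carbons, all inside the 74-105 ppm window
                "peaks": [
                    (103.0, 0.5, 0.12),
                    (99.0, 0.5, 0.10),
                    (90.0, 0.6, 0.18),
                    (84.0, 0.6, 0.25),
                    (77.0, 0.6, 0.35),
                ],
                "biomass_by_day": {1: 0.180, 2: 0.300, 3: 0.2364, 4: 0.0857, 5: 0.058},
                "mobile_fraction_by_day": {1: 0.94, 2: 0.94, 3: 0.84, 4: 0.78, 5: 0.71},
                "t1_mobile_s": 0.5,
                "t1_rigid_s": 20.0,
            },
            "protein": {
                # aliphatic/aromatic CH plus a carbonyl line outside the
                # quantification windows (region-based totals are partial)
                "peaks": [
                    (17.0, 0.8, 0.16),
                    (23.0, 0.8, 0.12),
                    (40.0, 0.9, 0.28),
                    (43.5, 0.9, 0.10),
                    (115.0, 1.0, 0.08),
                    (136.0, 1.0, 0.09),
                    (155.0, 1.0, 0.07),
                    (175.0, 1.0, 0.10),
                ],
                "biomass_by_day": {1: 0.400, 2: 0.500, 3: 0.2536, 4: 0.0971, 5: 0.062},
                "mobile_fraction_by_day": {1: 0.87, 2: 0.87, 3: 0.75, 4: 0.75, 5: 0.74},
                "t1_mobile_s": 0.5,
                "t1_rigid_s": 20.0,
            },
            "lipid": {
                # acyl-chain CH2 in the 29-34 ppm gap and olefinic carbons in
                # the 124-132 ppm gap, excluded from the protein windows
                "peaks": [(30.0, 0.8, 0.5), (32.5, 0.8, 0.3), (129.0, 1.0, 0.2)],
                "biomass_by_day": {1: 0.010, 2: 0.010, 3: 0.008, 4: 0.070, 5: 0.042},
                "mobile_fraction_by_day": {1: 0.95, 2: 0.95, 3: 0.95, 4: 0.95, 5: 0.95},
                "t1_mobile_s": 0.5,
                "t1_rigid_s": 20.0,
            },
        },
        "sugars": {
            # families: glucan scaffold (Glc), its uronic-acid side chain
            # (GlcA), medium-partitioned galactans (Gal-based), and cell-wall
            # peptidoglycan sugars (GlcNAc/MurNAc); GlcN is never detected in
            # the medium.
            "Glc": {
                "family": "glucan",
                "biofilm_by_day": {1: 6.0, 2: 10.0, 3: 7.0, 4: 4.5, 5: 3.5},
                "ratio_by_day": {1: 9.0, 2: 8.0, 3: 6.0, 4: 5.0, 5: 4.5},
            },
            "GlcA": {
                "family": "uronic",
                "biofilm_by_day": {1: 0.8, 2: 1.2, 3: 1.5, 4: 1.0, 5: 0.9},
                "ratio_by_day": {1: None, 2: 1.5, 3: 3.5, 4: 4.2, 5: 5.5},
            },
            "GlcN": {
                "family": "glucan",
                "biofilm_by_day": {1: 0.9, 2: 1.1, 3: 0.8, 4: 0.1, 5: 0.05},
                "ratio_by_day": {1: None, 2: None, 3: None, 4: None, 5: None},
            },
            "GlcNAc": {
                "family": "peptidoglycan",
                "biofilm_by_day": {1: 0.8, 2: 1.1, 3: 1.3, 4: 1.0, 5: 0.8},
                "ratio_by_day": {1: 2.1, 2: 2.0, 3: 2.2, 4: 1.8, 5: 1.6},
            },
            "MurNAc": {
                "family": "peptidoglycan",
                "biofilm_by_day": {1: 0.6, 2: 0.9, 3: 1.1, 4: 0.85, 5: 0.7},
                "ratio_by_day": {1: 2.2, 2: 2.1, 3: 2.3, 4: 1.9, 5: 1.7},
            },
            "Gal": {
                "family": "galactan",
                "biofilm_by_day": {1: 1.5, 2: 2.2, 3: 1.6, 4: 0.8, 5: 0.4},
                "ratio_by_day": {1: 0.55, 2: 0.50, 3: 0.40, 4: 0.30, 5: 0.25},
            },
            "GalN": {
                "family": "galactan",
                "biofilm_by_day": {1: 0.5, 2: 0.8, 3: 1.0, 4: 0.2, 5: 0.05},
                "ratio_by_day": {1: 0.56, 2: 0.51, 3: 0.41, 4: 0.31, 5: 0.26},
            },
            "GalNAc": {
                "family": "galactan",
                "biofilm_by_day": {1: 0.4, 2: 0.7, 3: 0.9, 4: 0.35, 5: 0.15},
                "ratio_by_day": {1: 0.54, 2: 0.49, 3: 0.39, 4: 0.29, 5: 0.24},
            },
        },
        "t1_sites": {
            "Glc-C1": 0.9,
            "Gal-C1": 0.7,
            "GlcA-C1": 1.2,
            "GlcNAc-C1": 2.0,
            "MurNAc-C1": 2.6,
        },
        "dipshift_sites": {
            "PG-GlcNAc-C1": ("CH", 0.72),
            "PG-MurNAc-C3": ("CH", 0.57),
            "TasA-CA": ("CH", 1.00),
            "TasA-CB": ("CH2", 0.73),
            "PG-C6": ("CH2", 0.49),
        },
        # mobile-phase 2D peak-volume categories; protein day 2 anchors the
        # normalized-absolute scale at 100
        "mobile_categories": {
            "proteins": {1: 60.0, 2: 100.0, 3: 50.72, 4: 19.41, 5: 15.0},
            "exopolysaccharides": {1: 40.0, 2: 66.6, 3: 52.42, 4: 18.99, 5: 17.0},
            "bacteria-related": {1: 15.0, 2: 21.6, 3: 26.9, 4: 22.0, 5: 18.0},
            "nucleotides": {1: 3.0, 2: 5.0, 3: 2.5, 4: 1.0, 5: 0.0},
            "N-acetyl": {1: 4.0, 2: 6.0, 3: 8.0, 4: 6.0, 5: 5.0},
            "lipids/biosurfactants": {1: 0.3, 2: 0.25, 3: 0.2, 4: 1.8, 5: 1.2},
            "unknown": {1: 2.0, 2: 4.0, 3: 3.0, 4: 2.0, 5: 1.5},
        },
        "sample_mass_mg_by_day": {1: 30.0, 2: 30.0, 3: 30.0, 4: 30.0, 5: 30.0},
        "scans_per_mode": {"qDP": 256, "DP2s": 1024, "CP": 2048},
    }


_SCALAR_KEYS = {
    "days", "noise_sigma", "ir_noise_sigma", "dipshift_noise_sigma",
    "sugar_noise_cv", "ppm_axis", "mas_rate_khz", "cp_efficiency",
    "sample_mass_mg_by_day", "scans_per_mode", "t1_sites", "dipshift_sites",
    "mobile_categories", "ir_delay_factors",
}


def build_scenario(config: dict | None = None, seed: int = 0) -> ScenarioSpec:
    """Resolve a (possibly partial) configuration into a ScenarioSpec.

    ``config`` overrides the defaults key by key; ``components`` and
    ``sugars`` sections replace the default section entirely when given.
    Unknown keys raise a :class:`ConfigurationError` naming the key.
    """
    base = default_config()
    config = config or {}
    for key, value in config.items():
        if key in ("components", "sugars"):
            base[key] = value
        elif key in _SCALAR_KEYS:
            base[key] = value
        else:
            raise ConfigurationError(f"unknown scenario key {key!r}")
    components = []
    for name, c in base["components"].items():
        extra = set(c) - {
            "peaks", "biomass_by_day", "mobile_fraction_by_day", "t1_mobile_s", "t1_rigid_s"
        }
        if extra:
            raise ConfigurationError(f"components.{name}: unknown key(s) {sorted(extra)}")
        components.append(
            ComponentSpec(
                name=name,
                peaks=[tuple(p) for p in c["peaks"]],
                biomass_by_day=c["biomass_by_day"],
                mobile_fraction_by_day=c["mobile_fraction_by_day"],
                t1_mobile_s=c.get("t1_mobile_s", 0.5),
                t1_rigid_s=c.get("t1_rigid_s", 20.0),
            )
        )
    sugars = []
    for name, s in base["sugars"].items():
        extra = set(s) - {"family", "biofilm_by_day", "ratio_by_day"}
        if extra:
            raise ConfigurationError(f"sugars.{name}: unknown key(s) {sorted(extra)}")
        sugars.append(
            SugarSpec(
                name=name,
                family=s["family"],
                biofilm_by_day=s["biofilm_by_day"],
                ratio_by_day=s["ratio_by_day"],
            )
        )
    scenario = ScenarioSpec(
        days=base["days"],
        components=components,
        sugars=sugars,
        t1_sites={k: float(v) for k, v in base["t1_sites"].items()},
        dipshift_sites={k: (str(m), float(s)) for k, (m, s) in base["dipshift_sites"].items()},
        mobile_categories=base["mobile_categories"],
        seed=int(seed),
        noise_sigma=float(base["noise_sigma"]),
        ir_noise_sigma=float(base["ir_noise_sigma"]),
        dipshift_noise_sigma=float(base["dipshift_noise_sigma"]),
        sugar_noise_cv=float(base["sugar_noise_cv"]),
        ppm_axis=tuple(base["ppm_axis"]),
        mas_rate_khz=float(base["mas_rate_khz"]),
        sample_mass_mg_by_day=base["sample_mass_mg_by_day"],
        scans_per_mode=base["scans_per_mode"],
        cp_efficiency=float(base["cp_efficiency"]),
        ir_delay_factors=tuple(base.get("ir_delay_factors", DEFAULT_IR_DELAY_FACTORS)),
    )
    for comp in scenario.components:
        for d in scenario.days:
            for key, mapping in (
                ("biomass_by_day", comp.biomass_by_day),
                ("mobile_fraction_by_day", comp.mobile_fraction_by_day),
            ):
                if d not in mapping:
                    raise ConfigurationError(f"components.{comp.name}.{key}: missing day {d}")
    return scenario


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True values of every quantity the pipeline estimates downstream."""

    seed: int
    total_biomass_by_day: dict[int, float]
    biomass_by_day: dict[str, dict[int, float]]
    mobile_fraction_by_day: dict[str, dict[int, float]]  # includes "overall"
    t1_by_site: dict[str, float]
    order_parameter_by_site: dict[str, dict]
    sugar_biofilm: dict[str, dict[int, float]]
    sugar_medium: dict[str, dict[int, float | None]]
    sugar_cluster_labels: dict[str, str]
    category_quantity_by_day: dict[str, dict[int, float]]

    def to_json(self) -> str:
        def conv(obj):
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return json.dumps({k: conv(v) for k, v in self.__dict__.items()},
                          indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)

        def intkeys(d):
            return {int(k): v for k, v in d.items()}

        return cls(
            seed=raw["seed"],
            total_biomass_by_day=intkeys(raw["total_biomass_by_day"]),
            biomass_by_day={c: intkeys(v) for c, v in raw["biomass_by_day"].items()},
            mobile_fraction_by_day={
                c: intkeys(v) for c, v in raw["mobile_fraction_by_day"].items()
            },
            t1_by_site=raw["t1_by_site"],
            order_parameter_by_site=raw["order_parameter_by_site"],
            sugar_biofilm={s: intkeys(v) for s, v in raw["sugar_biofilm"].items()},
            sugar_medium={s: intkeys(v) for s, v in raw["sugar_medium"].items()},
            sugar_cluster_labels=raw["sugar_cluster_labels"],
            category_quantity_by_day={
                c: intkeys(v) for c, v in raw["category_quantity_by_day"].items()
            },
        )


def ground_truth(scenario: ScenarioSpec) -> GroundTruth:
    """Assemble the GroundTruth record for a scenario."""
    biomass = {c.name: dict(c.biomass_by_day) for c in scenario.components}
    total = {
        d: sum(c.biomass_by_day[d] for c in scenario.components) for d in scenario.days
    }
    mobile: dict[str, dict[int, float]] = {
        c.name: dict(c.mobile_fraction_by_day) for c in scenario.components
    }
    mobile["overall"] = {
        d: (
            sum(c.biomass_by_day[d] * c.mobile_fraction_by_day[d] for c in scenario.components)
            / total[d]
            if total[d] > 0
            else float("nan")
        )
        for d in scenario.days
    }
    medium = {
        s.name: {
            d: (None if s.ratio_by_day.get(d) is None else s.biofilm_by_day[d] / s.ratio_by_day[d])
            for d in scenario.days
        }
        for s in scenario.sugars
    }
    return GroundTruth(
        seed=scenario.seed,
        total_biomass_by_day=total,
        biomass_by_day=biomass,
        mobile_fraction_by_day=mobile,
        t1_by_site=dict(scenario.t1_sites),
        order_parameter_by_site={
            site: {"multiplicity": m, "order_parameter": s}
            for site, (m, s) in scenario.dipshift_sites.items()
        },
        sugar_biofilm={s.name: dict(s.biofilm_by_day) for s in scenario.sugars},
        sugar_medium=medium,
        sugar_cluster_labels={s.name: s.family for s in scenario.sugars},
        category_quantity_by_day={
            cat: dict(by_day) for cat, by_day in scenario.mobile_categories.items()
        },
    )


# --------------------------------------------------------------------------
# emitters
# --------------------------------------------------------------------------


def _lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian profile."""
    return (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def _phase_weights(mode: str, t1_mobile: float, t1_rigid: float, cp_eff: float):
    if mode == "qDP":
        return 1.0, 1.0
    if mode == "DP2s":
        rd = SHORT_RECYCLE_DELAY_S
        return 1.0 - np.exp(-rd / t1_mobile), 1.0 - np.exp(-rd / t1_rigid)
    if mode == "CP":
        return 0.0, cp_eff
    raise InputError(f"unknown polarization mode {mode!r}; expected one of {MODES}")


def render_spectrum(scenario: ScenarioSpec, day: int, mode: str) -> Spectrum1D:
    """Render the 1D spectrum of one day in one polarization mode.

    The noiseless qDP integral of each component equals its configured
    biomass times (sample mass x number of scans), so the quantification
    stage recovers the configured biomass density exactly up to Lorentzian
    tail truncation.
    """
    if mode not in MODES:
        raise InputError(f"unknown polarization mode {mode!r}; expected one of {MODES}")
    if day not in scenario.days:
        raise InputError(f"day {day} not in scenario days {scenario.days}")
    lo, hi, n = scenario.ppm_axis
    ppm = np.linspace(hi, lo, n)  # stored descending, NMR display convention
    signal = np.zeros_like(ppm)
    for comp in scenario.components:
        mf = comp.mobile_fraction_by_day[day]
        wm, wr = _phase_weights(mode, comp.t1_mobile_s, comp.t1_rigid_s, scenario.cp_efficiency)
        weight = mf * wm + (1.0 - mf) * wr
        amplitude = comp.biomass_by_day[day] * weight / comp.total_area()
        for center, hwhm, area in comp.peaks:
            signal += amplitude * area * _lorentzian(ppm, center, hwhm)
    mass = scenario.sample_mass_mg_by_day[day]
    n_scans = scenario.scans_per_mode[mode]
    intensity = signal * mass * n_scans
    if scenario.noise_sigma > 0:
        rng = _stream(scenario.seed, "spectrum", day, MODES.index(mode))
        intensity = intensity + rng.normal(0.0, scenario.noise_sigma, intensity.shape)
    return Spectrum1D(
        ppm,
        intensity,
        sample_mass_mg=mass,
        n_scans=n_scans,
        mode=mode,
        day=day,
        meta={
            "seed": scenario.seed,
            "synthetic": True,
            "quantitative": mode == "qDP",
        },
    )


def emit_inversion_recovery(
    scenario: ScenarioSpec,
    site: str,
    delays: np.ndarray | None = None,
    noise_sigma: float | None = None,
) -> dynamics.InversionRecoverySeries:
    """Inversion-recovery series ``1 - 2 exp(-t/T1)`` for one labeled site."""
    if site not in scenario.t1_sites:
        raise InputError(f"site {site!r} has no true T1 in the scenario")
    t1 = scenario.t1_sites[site]
    if delays is None:
        delays = t1 * np.asarray(scenario.ir_delay_factors, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise InputError("empty delay grid")
    intensities = 1.0 - 2.0 * np.exp(-delays / t1)
    sigma = scenario.ir_noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = _stream(scenario.seed, "ir:" + site)
        intensities = intensities + rng.normal(0.0, sigma, intensities.shape)
    return dynamics.InversionRecoverySeries(
        site=site, delays=delays, intensities=intensities, noise_sigma=sigma
    )


def emit_dipshift(
    scenario: ScenarioSpec,
    site: str,
    n_t1: int = 16,
    noise_sigma: float | None = None,
    rigid_limit_khz: float = dynamics.RIGID_LIMIT_CH_KHZ,
    scaling: float = dynamics.FSLG_SCALING,
) -> dynamics.DipshiftCurve:
    """Dipolar dephasing curve at the site's true effective coupling
    (order parameter x rigid-limit coupling)."""
    if site not in scenario.dipshift_sites:
        raise InputError(f"site {site!r} has no true order parameter in the scenario")
    mult, s = scenario.dipshift_sites[site]
    curve = dynamics.simulate_dipshift(
        s * rigid_limit_khz,
        multiplicity=mult,
        mas_rate_khz=scenario.mas_rate_khz,
        scaling=scaling,
        n_t1=n_t1,
        site=site,
    )
    sigma = scenario.dipshift_noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = _stream(scenario.seed, "dipshift:" + site)
        noisy = curve.intensities + rng.normal(0.0, sigma, curve.intensities.shape)
        curve = dynamics.DipshiftCurve(
            site=site,
            t1_frac=curve.t1_frac,
            intensities=np.clip(noisy, -1.0, 1.0),
            multiplicity=mult,
            mas_rate_khz=scenario.mas_rate_khz,
            noise_sigma=sigma,
            meta=curve.meta,
        )
    return curve


def emit_sugar_tables(scenario: ScenarioSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (sugar, day, integral) tables for biofilm and spent medium.

    Medium integrals are biofilm / partition-ratio; days where a sugar is
    undetected in the medium are emitted as missing (NaN), never zero.
    """
    if len({s.family for s in scenario.sugars}) < 2:
        raise ConfigurationError("sugars: need >= 2 families with distinct partitioning")
    rng = _stream(scenario.seed, "sugar")
    cv = scenario.sugar_noise_cv
    bio_rows, med_rows = [], []
    for s in scenario.sugars:
        for d in scenario.days:
            q = s.biofilm_by_day[d]
            jb = rng.lognormal(0.0, cv) if cv > 0 else 1.0
            bio_rows.append({"sugar": s.name, "day": d, "integral": q * jb})
            ratio = s.ratio_by_day.get(d)
            if ratio is None:
                med_rows.append({"sugar": s.name, "day": d, "integral": np.nan})
            else:
                jm = rng.lognormal(0.0, cv) if cv > 0 else 1.0
                med_rows.append({"sugar": s.name, "day": d, "integral": (q / ratio) * jm})
    return pd.DataFrame(bio_rows), pd.DataFrame(med_rows)


def emit_component_volumes(scenario: ScenarioSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-peak 2D volume table for the mobile-phase categories.

    Each category's quantity is split over two synthetic peaks (60/40) so
    the grouping stage has real aggregation work to do.  Returns the tidy
    table and the peak -> category map.
    """
    rows = []
    category_map: dict[str, str] = {}
    for cat, by_day in scenario.mobile_categories.items():
        slug = cat.replace("/", "-").replace(" ", "_")
        for i, frac in enumerate((0.6, 0.4)):
            peak = f"{slug}_pk{i + 1}"
            category_map[peak] = cat
            for d in scenario.days:
                if d in by_day:
                    rows.append({"peak": peak, "day": d, "volume": by_day[d] * frac})
    return pd.DataFrame(rows), category_map


# --------------------------------------------------------------------------
# dataset writer
# --------------------------------------------------------------------------


def write_dataset(scenario: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic dataset for a scenario.

    Layout::

        outdir/
          spectra/spectrum_d<day>_<mode>.tsv (+ .json sidecars)
          inversion_recovery.csv   site, delay_s, intensity, sigma
          dipshift.csv             site, multiplicity, t1_frac, intensity,
                                   sigma, mas_rate_khz
          sugar_biofilm.csv        sugar, day, integral
          sugar_medium.csv         sugar, day, integral
          peak_volumes.csv         peak, day, volume
          category_map.json        peak -> category
          ground_truth.json
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for day in scenario.days:
        for mode in MODES:
            spec = render_spectrum(scenario, day, mode)
            p = outdir / "spectra" / f"spectrum_d{day}_{mode}.tsv"
            spec.write(p)
            paths[f"spectrum_d{day}_{mode}"] = p

    ir_rows = []
    for site in scenario.t1_sites:
        ser = emit_inversion_recovery(scenario, site)
        for t, i in zip(ser.delays, ser.intensities):
            ir_rows.append(
                {"site": site, "delay_s": t, "intensity": i, "sigma": ser.noise_sigma}
            )
    paths["inversion_recovery"] = outdir / "inversion_recovery.csv"
    pd.DataFrame(ir_rows).to_csv(paths["inversion_recovery"], index=False, float_format="%.10g")

    ds_rows = []
    for site in scenario.dipshift_sites:
        curve = emit_dipshift(scenario, site)
        for t, i in zip(curve.t1_frac, curve.intensities):
            ds_rows.append(
                {
                    "site": site,
                    "multiplicity": curve.multiplicity,
                    "t1_frac": t,
                    "intensity": i,
                    "sigma": curve.noise_sigma,
                    "mas_rate_khz": curve.mas_rate_khz,
                }
            )
    paths["dipshift"] = outdir / "dipshift.csv"
    pd.DataFrame(ds_rows).to_csv(paths["dipshift"], index=False, float_format="%.10g")

    bio, med = emit_sugar_tables(scenario)
    paths["sugar_biofilm"] = outdir / "sugar_biofilm.csv"
    paths["sugar_medium"] = outdir / "sugar_medium.csv"
    bio.to_csv(paths["sugar_biofilm"], index=False, float_format="%.10g")
    med.to_csv(paths["sugar_medium"], index=False, float_format="%.10g")

    volumes, category_map = emit_component_volumes(scenario)
    paths["peak_volumes"] = outdir / "peak_volumes.csv"
    volumes.to_csv(paths["peak_volumes"], index=False, float_format="%.10g")
    paths["category_map"] = outdir / "category_map.json"
    paths["category_map"].write_text(json.dumps(category_map, indent=1, sort_keys=True) + "\n")

    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(ground_truth(scenario).to_json())
    return paths
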