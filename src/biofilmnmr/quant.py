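"""Quantification of 1D spectra into calibrated biomass densities.

The central calibrated quantity is the *carbon biomass density*: a
spectral integral normalized by sample mass and number of scans, which
is proportional to the carbon weight fraction of the sample and hence
comparable across samples harvested from different wells.  The *mobile
fraction* of a region is the ratio of its density in a short-recycle-
delay DP spectrum (which detects only fast-relaxing, mobile components)
to its density in the quantitative DP spectrum.

Component classes are quantified over fixed chemical-shift regions:
carbohydrates over 74–105 ppm, proteins over the combined, lipid-free
ranges 10–29, 34–48, 106–124 and 132–160 ppm.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .spectra import Spectrum1D

#: Default quantification regions (ppm, half-open [low, high)).
DEFAULT_REGIONS: dict[str, list[tuple[float, float]]] = {
    "carbohydrate": [(74.0, 105.0)],
    "protein": [(10.0, 29.0), (34.0, 48.0), (106.0, 124.0), (132.0, 160.0)],
}

#: The seven source categories used for mobile-phase semi-quantification.
COMPONENT_CATEGORIES = (
    "bacteria-related",
    "exopolysaccharides",
    "proteins",
    "nucleotides",
    "N-acetyl",
    "lipids/biosurfactants",
    "unknown",
)

#: Solution-state glycerol reference peaks (ppm) used for consumption tracking.
GLYCEROL_PEAKS_PPM = (65.187, 72.775)


@dataclass
class RegionSet:
    """Named lists of half-open ppm intervals, one list per component class."""

    regions: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGIONS.items()}
    )

    def __post_init__(self) -> None:
        for name, intervals in self.regions.items():
            if not intervals:
                raise InputError(f"region list for class {name!r} is empty")
            ivs = sorted((min(a, b), max(a, b)) for a, b in intervals)
            for (lo1, hi1), (lo2, _hi2) in zip(ivs, ivs[1:]):
                if lo2 < hi1:
                    raise InputError(
                        f"intervals of class {name!r} overlap: ({lo1}, {hi1}) and ({lo2}, ...)"
                    )
            self.regions[name] = ivs

    def __getitem__(self, name: str) -> list[tuple[float, float]]:
        return self.regions[name]

    def classes(self) -> list[str]:
        return list(self.regions)


def integrate_region(spectrum: Spectrum1D, interval: tuple[float, float]) -> float:
    """Trapezoidal integral of the spectrum over a ppm interval.

    The interval is clipped to the axis; its endpoints are linearly
    interpolated so that integrals over adjacent intervals add exactly.
    Independent of the storage direction of the ppm axis.
    """
    lo, hi = (min(interval), max(interval))
    if hi <= lo:
        raise InputError(f"empty interval {interval}")
    s = spectrum.ascending
    axis_lo, axis_hi = s.ppm[0], s.ppm[-1]
    lo_c, hi_c = max(lo, axis_lo), min(hi, axis_hi)
    if hi_c <= lo_c:
        raise InputError(
            f"interval ({lo}, {hi}) does not overlap axis ({axis_lo}, {axis_hi})"
        )
    inside = (s.ppm > lo_c) & (s.ppm < hi_c)
    x = np.concatenate(([lo_c], s.ppm[inside], [hi_c]))
    y = np.interp(x, s.ppm, s.intensity)
    return float(np.trapezoid(y, x))


def integrate_regions(spectrum: Spectrum1D, intervals: Sequence[tuple[float, float]]) -> float:
    """Sum of :func:`integrate_region` over a list of disjoint intervals."""
    return sum(integrate_region(spectrum, iv) for iv in intervals)


def carbon_biomass_density(
    spectrum: Spectrum1D,
    interval: tuple[float, float] | Sequence[tuple[float, float]] | None = None,
) -> float:
    """Carbon biomass density: integral / (sample mass × number of scans).

    With no interval, integrates the full axis.  ``interval`` may be a
    single (lo, hi) pair or a list of disjoint pairs.  Quantitative claims
    require a qDP spectrum; other modes produce a warning, not an error.
    """
    if spectrum.mode != "qDP":
        warnings.warn(
            f"density computed from a {spectrum.mode} spectrum is not quantitative",
            stacklevel=2,
        )
    if interval is None:
        s = spectrum.ascending
        area = float(np.trapezoid(s.intensity, s.ppm))
    elif np.ndim(interval[0]) == 0:
        area = integrate_region(spectrum, interval)  # type: ignore[arg-type]
    else:
        area = integrate_regions(spectrum, interval)  # type: ignore[arg-type]
    return area / (spectrum.sample_mass_mg * spectrum.n_scans)


def mobile_fraction(
    dp2s: Spectrum1D,
    qdp: Spectrum1D,
    interval: tuple[float, float] | Sequence[tuple[float, float]] | None = None,
) -> float:
    """Mobile fraction: density(2 s DP) / density(quantitative DP), clamped.

    Both spectra must come from the same day/sample; densities are
    calibrated per spectrum, so differing masses or scan counts are fine.
    Values outside [0, 1] (possible from noise) are clamped with a warning.
    """
    if dp2s.day != qdp.day:
        raise InputError(f"day mismatch: DP2s day {dp2s.day} vs qDP day {qdp.day}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        num = carbon_biomass_density(dp2s, interval)
        den = carbon_biomass_density(qdp, interval)
    if den <= 0:
        raise ComputationError(f"qDP density must be > 0, got {den}")
    frac = num / den
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"mobile fraction {frac:.4f} outside [0, 1]; clamped (likely noise)",
            stacklevel=2,
        )
        frac = min(max(frac, 0.0), 1.0)
    return frac


def _index_series(spectra: Iterable[Spectrum1D]) -> dict[tuple[int, str], Spectrum1D]:
    out: dict[tuple[int, str], Spectrum1D] = {}
    for s in spectra:
        key = (s.day, s.mode)
        if key in out:
            raise InputError(f"duplicate spectrum for day {s.day}, mode {s.mode}")
        out[key] = s
    return out


def component_quant(
    spectra: Iterable[Spectrum1D],
    regions: RegionSet | None = None,
    reference_day: int = 2,
) -> pd.DataFrame:
    """Per-class biomass densities and mobile fractions over the time course.

    Takes a series of qDP and DP2s spectra (one of each per day), integrates
    each class's regions, and returns a tidy frame with columns ``day``,
    ``component``, ``density``, ``relative_density`` (internally normalized
    so the reference day equals 1.0) and ``mobile_fraction``.
    """
    regions = regions or RegionSet()
    by_key = _index_series(spectra)
    days = sorted({d for d, _ in by_key})
    missing = [
        f"day {d} {mode}" for d in days for mode in ("qDP", "DP2s") if (d, mode) not in by_key
    ]
    if missing:
        raise InputError("missing day/mode pairings: " + ", ".join(missing))
    if reference_day not in days:
        raise InputError(f"reference day {reference_day} not in series (days {days})")
    rows = []
    for cls in regions.classes():
        dens = {d: carbon_biomass_density(by_key[(d, "qDP")], regions[cls]) for d in days}
        ref = dens[reference_day]
        if ref <= 0:
            raise ComputationError(f"reference-day density for {cls!r} is {ref}")
        for d in days:
            rows.append(
                {
                    "day": d,
                    "component": cls,
                    "density": dens[d],
                    "relative_density": dens[d] / ref,
                    "mobile_fraction": mobile_fraction(
                        by_key[(d, "DP2s")], by_key[(d, "qDP")], regions[cls]
                    ),
                }
            )
    return pd.DataFrame(rows)


def total_biomass_series(
    spectra: Iterable[Spectrum1D], reference_day: int = 2
) -> pd.DataFrame:
    """Full-axis biomass density and overall mobile fraction per day,
    normalized to the reference day (columns ``day``, ``density``,
    ``relative_density``, ``mobile_fraction``)."""
    by_key = _index_series(spectra)
    days = sorted({d for d, _ in by_key})
    missing = [
        f"day {d} {mode}" for d in days for mode in ("qDP", "DP2s") if (d, mode) not in by_key
    ]
    if missing:
        raise InputError("missing day/mode pairings: " + ", ".join(missing))
    dens = {d: carbon_biomass_density(by_key[(d, "qDP")]) for d in days}
    ref = dens.get(reference_day)
    if ref is None:
        raise InputError(f"reference day {reference_day} not in series (days {days})")
    rows = [
        {
            "day": d,
            "density": dens[d],
            "relative_density": dens[d] / ref,
            "mobile_fraction": mobile_fraction(by_key[(d, "DP2s")], by_key[(d, "qDP")]),
        }
        for d in days
    ]
    return pd.DataFrame(rows)


def track_peak_intensity(
    spectra: Iterable[Spectrum1D],
    center: float,
    window: float,
    method: str = "height",
) -> pd.Series:
    """Track one peak across days, normalized to the day of maximum.

    ``method='height'`` takes the maximum intensity within center ± window
    (the default, as used for glycerol consumption at 65.2 ppm);
    ``method='integral'`` integrates the window instead.
    """
    if not window > 0:
        raise InputError(f"window must be > 0, got {window}")
    if method not in ("height", "integral"):
        raise InputError(f"method must be 'height' or 'integral', got {method!r}")
    values: dict[int, float] = {}
    for s in spectra:
        asc = s.ascending
        lo, hi = center - window, center + window
        if hi < asc.ppm[0] or lo > asc.ppm[-1]:
            raise InputError(
                f"window ({lo}, {hi}) outside axis ({asc.ppm[0]}, {asc.ppm[-1]})"
            )
        if method == "height":
            mask = (asc.ppm >= lo) & (asc.ppm <= hi)
            values[s.day] = float(asc.intensity[mask].max())
        else:
            values[s.day] = integrate_region(s, (lo, hi))
    ser = pd.Series(values).sort_index()
    peak = ser.max()
    if peak <= 0:
        raise ComputationError("peak absent from every spectrum (max <= 0)")
    out = ser / peak
    out.index.name = "day"
    out.name = f"peak_{center}ppm"
    return out


def group_components(
    volumes: pd.DataFrame,
    category_map: Mapping[str, str],
    reference: tuple[str, int] = ("proteins", 2),
    reference_value: float = 100.0,
) -> pd.DataFrame:
    """Group per-peak 2D volumes into the seven source categories.

    ``volumes`` needs columns ``peak``, ``day``, ``volume``.  Every peak is
    assigned through ``category_map``; unmapped peaks fall into
    ``"unknown"``.  Returns a tidy frame with columns ``day``, ``category``,
    ``quantity`` (absolute, normalized so the reference category/day equals
    ``reference_value``) and ``proportion`` (percent of that day's total,
    summing to 100).
    """
    required = {"peak", "day", "volume"}
    if not required.issubset(volumes.columns):
        raise InputError(f"volume table must have columns {sorted(required)}")
    dup = volumes.duplicated(subset=["peak", "day"])
    if dup.any():
        bad = volumes.loc[dup, "peak"].unique().tolist()
        raise InputError(f"duplicated peak identifiers: {bad}")
    df = volumes.copy()
    df["category"] = [category_map.get(p, "unknown") for p in df["peak"]]
    grouped = df.groupby(["day", "category"], as_index=False)["volume"].sum()
    ref_cat, ref_day = reference
    ref_rows = grouped[(grouped["category"] == ref_cat) & (grouped["day"] == ref_day)]
    if ref_rows.empty or not ref_rows["volume"].iloc[0] > 0:
        raise InputError(
            f"reference category {ref_cat!r} on day {ref_day} absent or non-positive"
        )
    scale = reference_value / ref_rows["volume"].iloc[0]
    grouped["quantity"] = grouped["volume"] * scale
    totals = grouped.groupby("day")["volume"].transform("sum")
    grouped["proportion"] = 100.0 * grouped["volume"] / totals
    return grouped.drop(columns="volume")


def degradation_observations(
    component_table: pd.DataFrame,
    protein_category: str = "proteins",
    carbohydrate_category: str = "exopolysaccharides",
    intervals: tuple[int, int] = (3, 4),
) -> tuple[float, float, float, float]:
    """Day-over-day decreases of the two major categories.

    Returns ``(dp1, dp2, dc1, dc2)``: the protein and carbohydrate
    quantities degraded on the intervals ending on ``intervals[0]`` and
    ``intervals[1]`` (decrease of ``quantity`` from the previous day),
    ready for :func:`biofilmnmr.kinetics.solve_proportions`.
    """
    piv = component_table.pivot(index="day", columns="category", values="quantity")
    out = []
    for cat in (protein_category, carbohydrate_category):
        if cat not in piv.columns:
            raise InputError(f"category {cat!r} not in component table")
        for day in intervals:
            if day not in piv.index or day - 1 not in piv.index:
                raise InputError(f"days {day - 1} and {day} required for interval 'day {day}'")
            out.append(float(piv.loc[day - 1, cat] - piv.loc[day, cat]))
    return tuple(out)  # type: ignore[return-value]
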