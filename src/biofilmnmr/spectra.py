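"""Frequency-domain 1D NMR spectra and their plain-text serialization.

A :class:`Spectrum1D` is a processed spectrum: a ppm axis, per-point
intensities and the acquisition metadata needed for quantitative
calibration (sample mass, number of scans, polarization mode).  Spectra
are stored on disk as a two-column numeric text file (ppm, intensity)
with a JSON metadata sidecar, so datasets remain diff-able and portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError

#: Polarization modes understood by the pipeline.
#: qDP  — direct polarization with a long recycle delay (quantitative)
#: DP2s — direct polarization with a 2 s recycle delay (mobile-selective)
#: CP   — cross polarization (rigid-selective, non-quantitative)
MODES = ("qDP", "DP2s", "CP")

#: Recycle delay (s) of the mobile-selective DP experiment.
SHORT_RECYCLE_DELAY_S = 2.0


@dataclass
class Spectrum1D:
    """A processed 1D ¹³C spectrum with quantification metadata.

    Parameters
    ----------
    ppm : array-like
        Chemical-shift axis in ppm, strictly monotone (either direction;
        NMR display convention stores it descending).
    intensity : array-like
        Intensity per point, arbitrary units.
    sample_mass_mg : float
        Mass of sample packed in the rotor, mg.  Must be positive.
    n_scans : int
        Number of co-added scans (NS).  Must be >= 1.
    mode : str
        One of :data:`MODES`.
    day : int
        Sampling time point in days.
    meta : dict
        Free-form extra metadata (seed, noise level, ...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_mass_mg: float
    n_scans: int
    mode: str
    day: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise InputError("ppm axis must be 1-D with at least 2 points")
        if self.ppm.shape != self.intensity.shape:
            raise InputError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("ppm axis must be strictly monotone")
        if not self.sample_mass_mg > 0:
            raise InputError(f"sample_mass_mg must be > 0, got {self.sample_mass_mg}")
        if int(self.n_scans) < 1:
            raise InputError(f"n_scans must be >= 1, got {self.n_scans}")
        self.n_scans = int(self.n_scans)
        if self.mode not in MODES:
            raise InputError(f"unknown polarization mode {self.mode!r}; expected one of {MODES}")

    @property
    def ascending(self) -> "Spectrum1D":
        """Return a view of this spectrum with an ascending ppm axis."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return Spectrum1D(
            self.ppm[::-1].copy(),
            self.intensity[::-1].copy(),
            self.sample_mass_mg,
            self.n_scans,
            self.mode,
            self.day,
            dict(self.meta),
        )

    # ---------------------------------------------------------------- I/O

    def write(self, data_path: str | Path) -> None:
        """Write the spectrum as 2-column text plus a ``.json`` sidecar."""
        data_path = Path(data_path)
        np.savetxt(
            data_path,
            np.column_stack([self.ppm, self.intensity]),
            fmt="%.10g",
            header="ppm\tintensity",
            delimiter="\t",
        )
        sidecar = {
            "sample_mass_mg": self.sample_mass_mg,
            "n_scans": self.n_scans,
            "mode": self.mode,
            "day": self.day,
            "meta": self.meta,
        }
        data_path.with_suffix(data_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, data_path: str | Path) -> "Spectrum1D":
        """Read a spectrum written by :meth:`write` (or any 2-column text
        file accompanied by a ``<name>.json`` sidecar)."""
        data_path = Path(data_path)
        arr = np.loadtxt(data_path)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InputError(f"{data_path}: expected two numeric columns (ppm, intensity)")
        sidecar_path = data_path.with_suffix(data_path.suffix + ".json")
        if not sidecar_path.exists():
            raise InputError(f"metadata sidecar not found: {sidecar_path}")
        side = json.loads(sidecar_path.read_text())
        return cls(
            arr[:, 0],
            arr[:, 1],
            sample_mass_mg=float(side["sample_mass_mg"]),
            n_scans=int(side["n_scans"]),
            mode=str(side["mode"]),
            day=int(side["day"]),
            meta=dict(side.get("meta", {})),
        )
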