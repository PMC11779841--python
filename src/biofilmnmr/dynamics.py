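"""¹³C T1 relaxation fitting and DIPSHIFT order-parameter analysis.

Two dynamics observables are extracted per resolved carbon site:

* **T1** from inversion-recovery series, fitted with the three-parameter
  exponential ``I(t) = A + B exp(-t / T1)`` (robust to imperfect
  inversion; ``B < 0`` for inversion recovery).

* **Order parameter S** from DIPSHIFT dipolar dephasing curves.  Under
  magic-angle spinning the heteronuclear C–H dipolar frequency of a
  crystallite with orientation (β, γ) is time modulated,

      ν(t) = (δ/2) [ √2 sin 2β cos(γ + ωr t) − sin²β cos(2γ + 2ωr t) ],

  where δ is the (FSLG-scaled) effective coupling and ωr the rotor
  frequency.  The dephasing signal over one rotor period is the powder
  average of ``cos Φ(t₁)`` with ``Φ`` the accumulated phase; for a CH₂
  group it is the powder average of the product of the two C–H cosine
  factors with tetrahedral inter-vector geometry.  The phase integral
  refocuses at full rotor periods (rotor echo) and the curve is symmetric
  about half a rotor period.  Fitting simulated curves to a measured one
  over the effective coupling, and dividing by the rigid-limit one-bond
  coupling, yields ``S = δ_eff / δ_rigid ∈ [0, 1]`` — 1 fully rigid,
  0 isotropically mobile.

Both fitters are scikit-learn style estimators; :func:`fit_t1` and
:func:`fit_order_parameter` are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from sklearn.base import BaseEstimator

from .errors import FitError, InputError

#: Rigid-limit one-bond C-H dipolar coupling (kHz) for r_CH ~ 1.1 A.
RIGID_LIMIT_CH_KHZ = 22.7

#: Theoretical FSLG homonuclear-decoupling scaling factor, 1/sqrt(3).
FSLG_SCALING = float(1.0 / 3.0**0.5)

#: Default MAS rate (kHz) for DIPSHIFT simulation.  Slow spinning deepens
#: the dephasing and hence the coupling sensitivity; 7 kHz is a typical
#: choice for non-constant-time DIPSHIFT.  Configurable everywhere.
DEFAULT_MAS_KHZ = 7.0

#: H-C-H tetrahedral angle (rad) used for the CH2 two-vector geometry.
_TETRAHEDRAL_RAD = np.deg2rad(109.47)

MULTIPLICITIES = ("CH", "CH2")


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class InversionRecoverySeries:
    """Inversion-recovery intensities for one site: delays in s."""

    site: str
    delays: np.ndarray
    intensities: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size == 0:
            raise InputError("empty delay grid")
        if self.delays.shape != self.intensities.shape:
            raise InputError("delays/intensities length mismatch")
        if np.any(self.delays < 0):
            raise InputError("delays must be >= 0")
        if np.unique(self.delays).size < 4:
            raise InputError("need >= 4 distinct delays to fit 3 parameters")


@dataclass
class T1Fit:
    """Result of a three-parameter inversion-recovery fit."""

    site: str
    t1: float
    a: float
    b: float
    residual_norm: float
    converged: bool


@dataclass
class DipshiftCurve:
    """Normalized dipolar dephasing curve over one rotor period.

    ``t1_frac`` is the dipolar evolution time as a fraction of the rotor
    period, in [0, 1]; intensities are normalized to the t=0 point.
    """

    site: str
    t1_frac: np.ndarray
    intensities: np.ndarray
    multiplicity: str
    mas_rate_khz: float = DEFAULT_MAS_KHZ
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t1_frac = np.asarray(self.t1_frac, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.t1_frac.size < 2:
            raise InputError("need at least 2 evolution-time points")
        if self.t1_frac.shape != self.intensities.shape:
            raise InputError("times/intensities length mismatch")
        if np.any((self.t1_frac < 0) | (self.t1_frac > 1)):
            raise InputError("evolution times must be fractions of the rotor period in [0, 1]")
        if self.multiplicity not in MULTIPLICITIES:
            raise InputError(
                f"multiplicity must be one of {MULTIPLICITIES}, got {self.multiplicity!r}"
            )
        if not self.mas_rate_khz > 0:
            raise InputError("MAS rate must be > 0")


@dataclass
class OrderParameterFit:
    """Effective coupling and order parameter for one site."""

    site: str
    coupling_khz: float
    order_parameter: float
    rigid_limit_khz: float
    scaling: float
    residual_norm: float


# --------------------------------------------------------------------------
# inversion-recovery model and fitting
# --------------------------------------------------------------------------


def recovery_model(t, a, b, t1):
    """Three-parameter recovery ``a + b exp(-t/t1)`` (``b < 0`` after inversion)."""
    return a + b * np.exp(-np.asarray(t, dtype=float) / t1)


class InversionRecoveryT1(BaseEstimator):
    """Least-squares estimator for the inversion-recovery time constant.

    Fits ``I(t) = A + B exp(-t/T1)`` to (delay, intensity) pairs.

    Parameters
    ----------
    max_t1_s : float
        Upper bound (s) for the T1 search; hitting it raises a fit error.

    Attributes
    ----------
    t1_ : float
        Fitted relaxation time (s).
    offset_, scale_ : float
        Fitted ``A`` and ``B``.
    residual_norm_ : float
        Euclidean norm of the fit residuals.
    """

    def __init__(self, max_t1_s: float = 100.0):
        self.max_t1_s = max_t1_s

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        I = np.asarray(y, dtype=float).reshape(-1)
        if t.size != I.size:
            raise InputError("X and y must have the same length")
        if np.unique(t).size < 4:
            raise InputError("need >= 4 distinct delays")
        if np.ptp(I) == 0:
            raise FitError("constant intensities: recovery amplitude is zero")
        a0 = I[np.argmax(t)]
        b0 = I[np.argmin(t)] - a0
        if b0 == 0:
            b0 = -np.ptp(I)
        # initial T1 from the delay where the recovery is ~63% complete
        prog = (I - I[np.argmin(t)]) / (a0 - I[np.argmin(t)]) if a0 != I[np.argmin(t)] else None
        t1_0 = max(t.max() / 3.0, 1e-3)
        if prog is not None:
            crossed = t[prog >= 0.632]
            if crossed.size:
                t1_0 = max(float(crossed.min()), 1e-3)
        try:
            popt, _ = curve_fit(
                recovery_model,
                t,
                I,
                p0=(a0, b0, t1_0),
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, self.max_t1_s]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
            raise FitError(f"inversion-recovery fit did not converge: {exc}") from exc
        a, b, t1 = popt
        if not np.isfinite(t1) or t1 <= 0:
            raise FitError(f"non-physical T1 from fit: {t1}")
        if t1 >= 0.999 * self.max_t1_s:
            raise FitError(f"T1 hit the search bound ({self.max_t1_s} s); fit unreliable")
        self.offset_, self.scale_, self.t1_ = float(a), float(b), float(t1)
        self.residual_norm_ = float(np.linalg.norm(I - recovery_model(t, a, b, t1)))
        return self

    def predict(self, X):
        return recovery_model(np.asarray(X, dtype=float).reshape(-1),
                              self.offset_, self.scale_, self.t1_)


def fit_t1(series: InversionRecoverySeries, max_t1_s: float = 100.0) -> T1Fit:
    """Fit the three-parameter recovery model to one series."""
    est = InversionRecoveryT1(max_t1_s=max_t1_s).fit(series.delays, series.intensities)
    return T1Fit(
        site=series.site,
        t1=est.t1_,
        a=est.offset_,
        b=est.scale_,
        residual_norm=est.residual_norm_,
        converged=True,
    )


# --------------------------------------------------------------------------
# DIPSHIFT simulation
# --------------------------------------------------------------------------


def _phase_factor(beta, gamma, x):
    """Dimensionless accumulated dipolar phase A(β, γ; x) with x = ωr·t.

    Φ = (δ/(2 f_r)) · A where δ and f_r share units.  Broadcasts over
    orientation and time axes.
    """
    s2b = np.sin(2.0 * beta)
    sb2 = np.sin(beta) ** 2
    term1 = np.sqrt(2.0) * s2b * (np.sin(gamma + x) - np.sin(gamma))
    term2 = 0.5 * sb2 * (np.sin(2.0 * gamma + 2.0 * x) - np.sin(2.0 * gamma))
    return term1 - term2


@lru_cache(maxsize=8)
def _ch_geometry(times_key: tuple, step_deg: float):
    """Powder grid (β sin-weighted × γ) phase factors for a single C-H vector.

    Returns (A, weights): A has shape (n_orient, n_times).
    """
    x = 2.0 * np.pi * np.asarray(times_key)
    step = np.deg2rad(step_deg)
    beta = np.arange(step / 2.0, np.pi, step)
    gamma = np.arange(step / 2.0, 2.0 * np.pi, step)
    B, G = np.meshgrid(beta, gamma, indexing="ij")
    w = np.sin(B).ravel()
    w = w / w.sum()
    A = _phase_factor(B.ravel()[:, None], G.ravel()[:, None], x[None, :])
    return A, w


@lru_cache(maxsize=8)
def _ch2_geometry(times_key: tuple, step_deg: float):
    """Powder-averaged geometry for the two C-H vectors of a CH2 group.

    The two unit vectors are separated by the tetrahedral angle and rigidly
    co-rotate; molecular orientations are sampled on a ZYZ Euler grid
    (α, β sin-weighted, γ).  Returns (A1, A2, weights).
    """
    x = 2.0 * np.pi * np.asarray(times_key)
    step = np.deg2rad(step_deg)
    half = _TETRAHEDRAL_RAD / 2.0
    u = np.array(
        [[np.sin(half), 0.0, np.cos(half)], [-np.sin(half), 0.0, np.cos(half)]]
    )  # (2, 3)
    alpha = np.arange(step / 2.0, 2.0 * np.pi, step)
    beta = np.arange(step / 2.0, np.pi, step)
    geuler = np.arange(step / 2.0, 2.0 * np.pi, step)
    A_list = []
    # Build rotated vectors v = Rz(alpha) Ry(beta) Rz(geuler) u for the full grid.
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(geuler), np.sin(geuler)
    # Rz(g) u  -> shape (n_g, 2, 3)
    vg = np.empty((geuler.size, 2, 3))
    vg[:, :, 0] = cg[:, None] * u[None, :, 0] - sg[:, None] * u[None, :, 1]
    vg[:, :, 1] = sg[:, None] * u[None, :, 0] + cg[:, None] * u[None, :, 1]
    vg[:, :, 2] = u[None, :, 2]
    # Ry(b) -> shape (n_b, n_g, 2, 3)
    vb = np.empty((beta.size, geuler.size, 2, 3))
    vb[..., 0] = cb[:, None, None] * vg[None, :, :, 0] + sb[:, None, None] * vg[None, :, :, 2]
    vb[..., 1] = vg[None, :, :, 1]
    vb[..., 2] = -sb[:, None, None] * vg[None, :, :, 0] + cb[:, None, None] * vg[None, :, :, 2]
    # Rz(a) -> shape (n_a, n_b, n_g, 2, 3)
    va = np.empty((alpha.size, beta.size, geuler.size, 2, 3))
    va[..., 0] = ca[:, None, None, None] * vb[None, ..., 0] - sa[:, None, None, None] * vb[None, ..., 1]
    va[..., 1] = sa[:, None, None, None] * vb[None, ..., 0] + ca[:, None, None, None] * vb[None, ..., 1]
    va[..., 2] = vb[None, ..., 2]
    w = np.broadcast_to(np.sin(beta)[None, :, None], va.shape[:3]).reshape(-1).copy()
    w = w / w.sum()
    v = va.reshape(-1, 2, 3)
    for i in range(2):
        vz = np.clip(v[:, i, 2], -1.0, 1.0)
        b_i = np.arccos(vz)
        g_i = np.arctan2(v[:, i, 1], v[:, i, 0])
        A_list.append(_phase_factor(b_i[:, None], g_i[:, None], x[None, :]))
    return A_list[0], A_list[1], w


def _resolve_powder_step(step: float | None, multiplicity: str) -> float:
    """Default quadrature step: 5° for the CH (β, γ) grid; 10° for the CH2
    three-Euler-angle grid (agrees with a 5° grid to <= 3.3e-4 absolute up
    to the rigid-limit coupling, at an eighth of the cost)."""
    if step is not None:
        return float(step)
    return 5.0 if multiplicity == "CH" else 10.0


def simulate_dipshift(
    coupling_khz: float,
    multiplicity: str = "CH",
    mas_rate_khz: float = DEFAULT_MAS_KHZ,
    scaling: float = FSLG_SCALING,
    n_t1: int = 16,
    powder_step_deg: float | None = None,
    times: np.ndarray | None = None,
    site: str = "sim",
) -> DipshiftCurve:
    """Simulate a powder-averaged DIPSHIFT dephasing curve.

    Parameters
    ----------
    coupling_khz : float
        Effective (motionally averaged) C-H dipolar coupling δ_eff in kHz,
        before homonuclear-decoupling scaling.
    multiplicity : {"CH", "CH2"}
        CH2 is modeled as the powder average of the product of two C-H
        dephasing factors with tetrahedral inter-vector geometry
        (cross-correlation between the two couplings is neglected).
    mas_rate_khz : float
        MAS rate in kHz; sets the rotor period.
    scaling : float
        Homonuclear-decoupling scaling factor applied to the coupling
        (FSLG: 1/√3 ≈ 0.577).
    n_t1 : int
        Number of evolution-time points over one rotor period (ignored
        when ``times`` is given).
    powder_step_deg : float
        Angular step of the powder grid (sin β weighted).
    times : array, optional
        Explicit evolution times as fractions of the rotor period.
    """
    if coupling_khz < 0:
        raise InputError(f"coupling must be >= 0, got {coupling_khz}")
    if multiplicity not in MULTIPLICITIES:
        raise InputError(f"multiplicity must be one of {MULTIPLICITIES}")
    if not mas_rate_khz > 0:
        raise InputError("MAS rate must be > 0")
    if times is None:
        if n_t1 < 2:
            raise InputError("n_t1 must be >= 2")
        times = np.linspace(0.0, 1.0, n_t1)
    times = np.asarray(times, dtype=float)
    times_key = tuple(np.round(times, 12))
    step = _resolve_powder_step(powder_step_deg, multiplicity)
    c = scaling * coupling_khz / (2.0 * mas_rate_khz)
    if c == 0.0:
        intensities = np.ones_like(times)
    elif multiplicity == "CH":
        A, w = _ch_geometry(times_key, step)
        intensities = w @ np.cos(c * A)
    else:
        A1, A2, w = _ch2_geometry(times_key, step)
        intensities = w @ (np.cos(c * A1) * np.cos(c * A2))
    return DipshiftCurve(
        site=site,
        t1_frac=times,
        intensities=intensities,
        multiplicity=multiplicity,
        mas_rate_khz=mas_rate_khz,
        meta={"coupling_khz": coupling_khz, "scaling": scaling,
              "powder_step_deg": step},
    )


# --------------------------------------------------------------------------
# order-parameter fitting
# --------------------------------------------------------------------------


class DipshiftOrderParameter(BaseEstimator):
    """Fit-by-simulation estimator for the C-H order parameter.

    A 1-D least-squares search over the effective coupling, evaluated by
    repeated :func:`simulate_dipshift` calls on the curve's own time grid
    (coarse scan + bounded scalar refinement).  The search runs over
    [0, 1.2 δ_rigid] so pathological fits surface instead of being
    silently clamped; the final S is clamped to [0, 1] with a warning.

    Parameters
    ----------
    rigid_limit_khz : float
        Rigid-limit one-bond C-H coupling δ_rigid (kHz).
    scaling : float
        Homonuclear-decoupling scaling factor.
    multiplicity : {"CH", "CH2"}
    mas_rate_khz : float
    powder_step_deg : float
    residual_threshold : float
        Residual norm above which a poor-fit warning is emitted.

    Attributes
    ----------
    coupling_ : float
        Best-fit effective coupling (kHz).
    order_parameter_ : float
        ``coupling_ / rigid_limit_khz``, clamped to [0, 1].
    residual_norm_ : float
    """

    def __init__(
        self,
        rigid_limit_khz: float = RIGID_LIMIT_CH_KHZ,
        scaling: float = FSLG_SCALING,
        multiplicity: str = "CH",
        mas_rate_khz: float = DEFAULT_MAS_KHZ,
        powder_step_deg: float | None = None,
        residual_threshold: float = 0.5,
    ):
        self.rigid_limit_khz = rigid_limit_khz
        self.scaling = scaling
        self.multiplicity = multiplicity
        self.mas_rate_khz = mas_rate_khz
        self.powder_step_deg = powder_step_deg
        self.residual_threshold = residual_threshold

    def _simulate(self, coupling, times):
        return simulate_dipshift(
            coupling,
            multiplicity=self.multiplicity,
            mas_rate_khz=self.mas_rate_khz,
            scaling=self.scaling,
            powder_step_deg=self.powder_step_deg,
            times=times,
        ).intensities

    def fit(self, X, y):
        times = np.asarray(X, dtype=float).reshape(-1)
        target = np.asarray(y, dtype=float).reshape(-1)
        if times.size != target.size:
            raise InputError("X and y must have the same length")
        if not self.rigid_limit_khz > 0:
            raise InputError("rigid-limit coupling must be > 0")
        hi = 1.2 * self.rigid_limit_khz

        def sse(coupling):
            return float(np.sum((self._simulate(coupling, times) - target) ** 2))

        grid = np.linspace(0.0, hi, 61)
        losses = np.array([sse(g) for g in grid])
        i = int(np.argmin(losses))
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, grid.size - 1)]
        if lo_b == hi_b:
            best = grid[i]
        else:
            res = minimize_scalar(
                sse, bounds=(lo_b, hi_b), method="bounded",
                options={"xatol": 1e-4 * self.rigid_limit_khz},
            )
            if not res.success:
                raise FitError(f"order-parameter search failed: {res.message}")
            best = float(res.x)
        self.coupling_ = best
        self.residual_norm_ = float(np.sqrt(sse(best)))
        s = best / self.rigid_limit_khz
        if s > 1.0:
            warnings.warn(
                f"fitted coupling {best:.3f} kHz exceeds the rigid limit "
                f"{self.rigid_limit_khz} kHz; order parameter clamped to 1",
                stacklevel=2,
            )
            s = 1.0
        self.order_parameter_ = s
        if self.residual_norm_ > self.residual_threshold:
            warnings.warn(
                f"poor dephasing fit (residual norm {self.residual_norm_:.3g})",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return self._simulate(self.coupling_, np.asarray(X, dtype=float).reshape(-1))


def fit_order_parameter(
    curve: DipshiftCurve,
    rigid_limit_khz: float = RIGID_LIMIT_CH_KHZ,
    scaling: float = FSLG_SCALING,
    powder_step_deg: float | None = None,
    residual_threshold: float = 0.5,
) -> OrderParameterFit:
    """Fit the effective coupling / order parameter of one dephasing curve."""
    est = DipshiftOrderParameter(
        rigid_limit_khz=rigid_limit_khz,
        scaling=scaling,
        multiplicity=curve.multiplicity,
        mas_rate_khz=curve.mas_rate_khz,
        powder_step_deg=powder_step_deg,
        residual_threshold=residual_threshold,
    ).fit(curve.t1_frac, curve.intensities)
    return OrderParameterFit(
        site=curve.site,
        coupling_khz=est.coupling_,
        order_parameter=est.order_parameter_,
        rigid_limit_khz=rigid_limit_khz,
        scaling=scaling,
        residual_norm=est.residual_norm_,
    )
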