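"""AFM force-spectroscopy analysis: contact-point estimation, Hertz
spherical-indenter fitting, and ISO-style line roughness.

Sign/unit conventions (documented once, tested by round-trip):

* approach = increasing piezo displacement z (nm); positive deflection d
  (nm) is repulsive;
* force F = k·d with the spring constant k in nN/nm, so F is in nN;
* indentation δ = (z − z0) − d (soft-sample convention);
* Young's modulus E is reported in kPa. Since 1 kPa ≡ 1 nN/µm², the Hertz
  prefactor needs no conversion constant when R is in µm and δ in µm:
  F = (4/3)·E/(1−ν²)·√R·δ^{3/2}.

The default fit window caps indentation at 250 nm (instrument trigger) and
the Poisson ratio defaults to 0.5 (incompressible cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .synth import SyntheticForceCurve, hertz_force

__all__ = [
    "ForceCurve",
    "HertzModel",
    "HertzFit",
    "to_force_indentation",
    "find_contact_point",
    "hertz_fit",
    "line_rms_roughness",
    "read_force_curve_csv",
    "analyze_curve",
]

MAX_INDENTATION_NM = 250.0
DEFAULT_NU = 0.5
DEFAULT_R_UM = 4.0


@dataclass
class ForceCurve:
    """Raw approach record: piezo z (nm), deflection d (nm), k (nN/nm),
    bead radius R (µm)."""

    z: np.ndarray
    d: np.ndarray
    k: float
    R: float = DEFAULT_R_UM
    nu: float = DEFAULT_NU
    approach_speed: float | None = None  # µm/s, metadata only

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.d = np.asarray(self.d, float)
        if self.z.shape != self.d.shape or self.z.size < 50:
            raise ValueError("z and d must be equal-length arrays of at least 50 samples")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("spring constant and bead radius must be positive")

    @classmethod
    def from_synthetic(cls, curve: SyntheticForceCurve) -> "ForceCurve":
        return cls(z=curve.z, d=curve.d, k=curve.k, R=curve.R, nu=curve.nu)


@dataclass
class HertzFit:
    E_kPa: float
    nu: float
    z0_nm: float
    rss_nN2: float
    max_indentation_used_nm: float
    n_points: int


def to_force_indentation(curve: ForceCurve, z0: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert a raw curve to (δ nm, F nN) given the contact point z0.

    The pre-contact deflection offset (mean d where z < z0) is removed
    before converting; only post-contact samples with δ > 0 are returned.
    """
    if not (curve.z.min() <= z0 <= curve.z.max()):
        raise ValueError("z0 outside the recorded z range")
    pre = curve.z < z0
    baseline = float(curve.d[pre].mean()) if pre.any() else 0.0
    d = curve.d - baseline
    F = curve.k * d
    delta = (curve.z - z0) - d
    keep = (curve.z >= z0) & (delta > 0)
    if not keep.any():
        raise ValueError("no post-contact points with positive indentation")
    return delta[keep], F[keep]


def _piecewise_rss(curve: ForceCurve, i: int, max_ind_nm: float) -> float:
    """RSS of (flat baseline before sample i) + (Hertz rise after)."""
    z, d, k = curve.z, curve.d, curve.k
    baseline = d[:i].mean()
    rss = float(np.sum((k * (d[:i] - baseline)) ** 2))
    dd = d[i:] - baseline
    F = k * dd
    delta = (z[i:] - z[i]) - dd
    ok = delta > 0
    if ok.sum() >= 3:
        x = (np.clip(delta[ok], 0, max_ind_nm * 10) / 1000.0) ** 1.5
        y = F[ok]
        s = float(x @ y / (x @ x)) if x @ x > 0 else 0.0
        s = max(s, 0.0)
        rss += float(np.sum((y - s * x) ** 2))
        rss += float(np.sum(F[~ok] ** 2))
    else:
        rss += float(np.sum(F**2))
    return rss


def _continuous_rss(curve: ForceCurve, z0: float) -> float:
    """RSS of baseline + Hertz rise for a continuous contact position."""
    z, d, k = curve.z, curve.d, curve.k
    pre = z < z0
    if pre.sum() < 3 or (~pre).sum() < 5:
        return np.inf
    baseline = d[pre].mean()
    dd = d - baseline
    F = k * dd
    rss = float(np.sum(F[pre] ** 2))
    delta = (z[~pre] - z0) - dd[~pre]
    ok = delta > 0
    if ok.sum() >= 3:
        x = (delta[ok] / 1000.0) ** 1.5
        y = F[~pre][ok]
        s = max(float(x @ y / (x @ x)), 0.0)
        rss += float(np.sum((y - s * x) ** 2)) + float(np.sum(F[~pre][~ok] ** 2))
    else:
        rss += float(np.sum(F[~pre] ** 2))
    return rss


def _deflection_model(z: np.ndarray, E: float, z0: float, k: float, R: float, nu: float) -> np.ndarray:
    """Forward model of the approach deflection: for z > z0 the piezo motion
    splits between indentation and deflection, δ + F(δ)/k = z − z0."""
    d = np.zeros_like(z)
    post = z > z0
    zz = z[post] - z0
    dlt = np.clip(zz, 1e-9, None)
    for _ in range(60):
        F = hertz_force(dlt, E, R, nu)
        dF = np.where(dlt > 0, 1.5 * F / np.clip(dlt, 1e-12, None), 0.0)
        step = (dlt + F / k - zz) / (1.0 + dF / k)
        dlt = np.clip(dlt - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-9:
            break
    d[post] = hertz_force(dlt, E, R, nu) / k
    return d


def find_contact_point(curve: ForceCurve, max_ind_nm: float = MAX_INDENTATION_NM,
                       refine: bool = True) -> float:
    """Contact point z0 by exhaustive piecewise change-point search.

    Every sample index is scored as a candidate change point between a flat
    baseline and a Hertz-shaped rise; the global RSS minimum wins. With
    ``refine`` (default) the winner is polished by a joint (E, z0)
    least-squares fit of the forward deflection model. The polish matters
    statistically: converting data to indentation before fitting feeds the
    deflection noise into δ itself (an errors-in-variables effect that
    biases z0 early by about a sample spacing), whereas fitting in
    deflection space is unbiased. Raises if the RSS profile is flat (no
    detectable contact).
    """
    from scipy.optimize import least_squares

    n = curve.z.size
    cands = np.arange(5, n - 10)
    rss = np.array([_piecewise_rss(curve, int(i), max_ind_nm) for i in cands])
    if np.ptp(rss) < 1e-12 * max(rss.max(), 1e-30):
        raise ValueError("no contact detected: change-point RSS profile is flat")
    i_best = int(cands[int(np.argmin(rss))])
    z_best = float(curve.z[i_best])
    if not refine:
        return z_best

    try:
        delta, F = to_force_indentation(curve, z_best)
        E_init = HertzModel(R_um=curve.R, nu=curve.nu,
                            max_indentation_nm=max_ind_nm).fit(delta, F).E_kPa_
    except ValueError:
        return z_best

    z, d = curve.z, curve.d

    def residuals(theta):
        E, z0 = theta
        pre = z < z0
        b = d[pre].mean() if pre.sum() > 2 else 0.0
        return (d - b) - _deflection_model(z, E, z0, curve.k, curve.R, curve.nu)

    lo_z, hi_z = float(z[3]), float(z[-10])
    sol = least_squares(residuals, [max(E_init, 1e-3), z_best],
                        bounds=([1e-4, lo_z], [1e4, hi_z]))
    return float(sol.x[1]) if sol.success else z_best


class HertzModel(BaseEstimator, RegressorMixin):
    """Spherical-indenter Hertz contact fit, E in kPa.

    A linear regression of F on δ^{3/2} through the origin inside the
    indentation window; the slope s gives E = (3/4)·s·(1−ν²)/√R.

    Parameters
    ----------
    R_um : bead radius, µm (the beads are measured individually, so this is
        per-fit data rather than a constant).
    nu : Poisson ratio, 0.5 for an incompressible cell.
    max_indentation_nm : fit window cap (instrument trigger), default 250.

    Attributes
    ----------
    E_kPa_ : fitted Young's modulus.
    slope_ : regression slope, nN/µm^{3/2}.
    rss_ : residual sum of squares, nN².
    """

    def __init__(self, R_um: float = DEFAULT_R_UM, nu: float = DEFAULT_NU,
                 max_indentation_nm: float = MAX_INDENTATION_NM, min_points: int = 10):
        self.R_um = R_um
        self.nu = nu
        self.max_indentation_nm = max_indentation_nm
        self.min_points = min_points

    def fit(self, delta_nm, F_nN):
        delta = np.asarray(delta_nm, float).ravel()
        F = np.asarray(F_nN, float).ravel()
        keep = (delta > 0) & (delta <= self.max_indentation_nm)
        if keep.sum() < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points with 0 < δ <= {self.max_indentation_nm} nm"
            )
        x = (delta[keep] / 1000.0) ** 1.5  # µm^1.5
        y = F[keep]
        slope = float(x @ y / (x @ x))
        if slope <= 0:
            raise ValueError("negative fitted slope: curve is not a repulsive contact")
        self.slope_ = slope
        self.E_kPa_ = 0.75 * slope * (1.0 - self.nu**2) / np.sqrt(self.R_um)
        self.rss_ = float(np.sum((y - slope * x) ** 2))
        self.n_points_ = int(keep.sum())
        self.max_indentation_used_nm_ = float(delta[keep].max())
        return self

    def predict(self, delta_nm):
        check_is_fitted(self, "E_kPa_")
        return hertz_force(np.asarray(delta_nm, float), self.E_kPa_, self.R_um, self.nu)


def hertz_fit(delta_nm, F_nN, R_um: float = DEFAULT_R_UM, nu: float = DEFAULT_NU,
              max_indentation_nm: float = MAX_INDENTATION_NM, z0_nm: float = np.nan) -> HertzFit:
    model = HertzModel(R_um=R_um, nu=nu, max_indentation_nm=max_indentation_nm).fit(delta_nm, F_nN)
    return HertzFit(
        E_kPa=float(model.E_kPa_),
        nu=nu,
        z0_nm=float(z0_nm),
        rss_nN2=model.rss_,
        max_indentation_used_nm=model.max_indentation_used_nm_,
        n_points=model.n_points_,
    )


def analyze_curve(curve: ForceCurve, max_indentation_nm: float = MAX_INDENTATION_NM) -> HertzFit:
    """Full single-curve pipeline: contact point → conversion → Hertz fit."""
    z0 = find_contact_point(curve, max_indentation_nm)
    delta, F = to_force_indentation(curve, z0)
    return hertz_fit(delta, F, R_um=curve.R, nu=curve.nu,
                     max_indentation_nm=max_indentation_nm, z0_nm=z0)


def line_rms_roughness(x_um, h_nm) -> float:
    """R_rms (nm): RMS height deviation from the least-squares mean line.

    The linear mean line levels any tilt of the scan, per the standard
    surface-texture convention; adding a constant or a linear ramp to the
    profile leaves R_rms unchanged.
    """
    x = np.asarray(x_um, float).ravel()
    h = np.asarray(h_nm, float).ravel()
    if x.shape != h.shape or x.size < 10:
        raise ValueError("profile needs at least 10 equal-length samples")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be monotone increasing")
    coef = np.polyfit(x, h, 1)
    res = h - np.polyval(coef, x)
    return float(np.sqrt(np.mean(res**2)))


def read_force_curve_csv(path, k: float | None = None, R: float = DEFAULT_R_UM,
                         nu: float = DEFAULT_NU) -> ForceCurve:
    """Read a ``z_nm, deflection_nm`` CSV; k/R/ν from the JSON sidecar when present."""
    import json
    import os

    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    side = str(path) + ".json"
    if os.path.exists(side):
        with open(side) as fh:
            meta = json.load(fh)
        k = meta.get("k_nN_per_nm", k)
        R = meta.get("R_um", R)
        nu = meta.get("nu", nu)
    if k is None:
        raise ValueError("spring constant k is required (argument or sidecar)")
    return ForceCurve(z=arr[:, 0], d=arr[:, 1], k=k, R=R, nu=nu)


def batch_fit(curves, max_indentation_nm: float = MAX_INDENTATION_NM) -> pd.DataFrame:
    """Fit a sequence of ForceCurve; one row per curve."""
    rows = []
    for i, c in enumerate(curves):
        fit = analyze_curve(c, max_indentation_nm)
        rows.append({"curve": i, "E_kPa": fit.E_kPa, "z0_nm": fit.z0_nm,
                     "rss_nN2": fit.rss_nN2, "n_points": fit.n_points})
    return pd.DataFrame(rows)
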