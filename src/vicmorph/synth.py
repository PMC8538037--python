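"""Synthetic ground-truth generators for every pipeline input.

The generators emulate the study conditions of a valve-interstitial-cell
culture experiment on flat glass versus fibrous nanostructured substrates:

* single-cell binary masks of the three morphology classes — small
  spindle-like smooth-muscle cells (SMc), intermediate elongated
  fibroblasts (Fib), and large cuspate myofibroblasts (myFib);
* nuclei (DAPI) fields with homogeneous Poisson placement at a prescribed
  density and a hard-core minimum separation;
* two-channel marker images (actin + vinculin punctae, stress-fiber
  filaments, or colocalized marker) painted at an exact area fraction;
* AFM force curves from the spherical-indenter Hertz contact law; and
* surface height profiles (flat or fibrous) at a prescribed RMS roughness.

Every generator is deterministic given its seed and records its ground
truth, so each downstream operator can be validated by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter, distance_transform_edt
from scipy.special import ellipe
from scipy.optimize import brentq
from shapely.geometry import Polygon
from skimage import draw

from .morphometry import CellMask, _min_rotated_rect_sides

__all__ = [
    "ShapeParams",
    "FieldParams",
    "CurveParams",
    "SyntheticForceCurve",
    "gen_cell_mask",
    "gen_nuclei_field",
    "gen_marker_field",
    "gen_force_curve",
    "gen_height_profile",
    "ellipse_doc",
    "aspect_for_doc",
    "write_field_tiff",
    "write_force_curve_csv",
]

#: Default camera sampling, µm per pixel (typical 10x objective + sCMOS).
DEFAULT_PIXEL_SIZE = 0.65

#: Areas below this are too coarse to rasterize faithfully; draws are
#: truncated here and a degenerate-shape error raised if requested directly.
MIN_AREA_UM2 = 50.0

#: Hard-core minimum separation between nucleus centroids, µm.
MIN_NUCLEUS_SEP_UM = 15.0

CLASS_NAMES = ("SMc", "Fib", "myFib")


@dataclass
class ShapeParams:
    """Generating distribution of one morphology class.

    ``elongation_range`` bounds the class's elongation band; draws within
    the band follow a symmetric Beta(3, 3), concentrating mass at the band
    centre so adjacent classes stay separable. ``n_cusps_range`` is an
    inclusive integer range sampled uniformly.
    """

    morph_class: str
    area_mean: float  # µm²
    area_sd: float  # µm²
    elongation_range: tuple[float, float]
    n_cusps_range: tuple[int, int]
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morph_class not in CLASS_NAMES:
            raise ValueError(f"morph_class must be one of {CLASS_NAMES}")
        if self.area_mean <= 0:
            raise ValueError("area_mean must be positive")
        lo, hi = self.elongation_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("elongation_range must be ordered within [0, 1)")
        clo, chi = self.n_cusps_range
        if not (0 <= clo <= chi):
            raise ValueError("n_cusps_range must be ordered with lower >= 0")


def default_shape_params(morph_class: str, pixel_size: float = DEFAULT_PIXEL_SIZE) -> ShapeParams:
    """Study-condition defaults per class: areas from the glass-control
    measurements, elongation bands inside the published class intervals,
    cusp ranges matching the drop/spindle/triangle calibration."""
    table = {
        "SMc": dict(area_mean=230.0, area_sd=102.0, elongation_range=(0.85, 0.97), n_cusps_range=(2, 2)),
        "Fib": dict(area_mean=480.0, area_sd=194.0, elongation_range=(0.57, 0.81), n_cusps_range=(2, 3)),
        "myFib": dict(area_mean=998.0, area_sd=408.0, elongation_range=(0.25, 0.55), n_cusps_range=(4, 8)),
    }
    return ShapeParams(morph_class=morph_class, pixel_size=pixel_size, **table[morph_class])


@dataclass
class FieldParams:
    density: float  # cells per mm²
    field_area: float = 0.15  # mm²
    n_fields: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")


@dataclass
class CurveParams:
    """Forward-model parameters of one AFM indentation.

    Defaults mirror the instrument configuration: a ~4 µm-radius glass bead
    on a soft cantilever (nominal 0.03 nN/nm), indentation triggered at
    250 nm, incompressible-sample Poisson ratio 0.5.
    """

    E_true: float  # kPa
    poisson_ratio: float = 0.5
    bead_radius: float = 4.0  # µm
    spring_constant: float = 0.03  # nN/nm
    max_indentation: float = 250.0  # nm
    noise_sd: float = 0.0  # nN, additive on force
    n_points: int = 500
    contact_offset: float = 500.0  # nm of pre-contact baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.bead_radius <= 0 or self.max_indentation <= 0:
            raise ValueError("bead_radius and max_indentation must be positive")


# ---------------------------------------------------------------------------
# cell masks
# ---------------------------------------------------------------------------

def _star_polygon(
    n_tips: int,
    elong: float,
    rng: np.random.Generator,
    tip_amp: float = 0.6,
    tip_width: float = 0.35,
    n_theta: int = 720,
) -> Polygon:
    """Smooth star polygon with ``n_tips`` protrusions at elongation ``elong``.

    Built as an ellipse-based radial profile multiplied by raised-cosine
    bumps. For elongated shapes (elong >= 0.4) the two major-axis ends are
    always sharpened into spindle tips and extra tips sit near the long
    axis, so the rendered protrusion count matches the requested one.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    aspect = 1.0 / (1.0 - elong)
    a, b = aspect, 1.0
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    def _bump(angles: list[float], half_w: float) -> np.ndarray:
        out = np.zeros_like(theta)
        for ang in angles:
            d = np.angle(np.exp(1j * (theta - ang)))
            inside = np.abs(d) < half_w
            out[inside] += np.cos(0.5 * np.pi * d[inside] / half_w) ** 2
        return out

    spindle = elong >= 0.56
    if n_tips > 0:
        if spindle:
            # spindle form: sharpened major-axis ends, extra tips flanking them;
            # side tips are additive with height tied to the long semi-axis so
            # they stay prominent despite the anisotropy
            ends = [0.0, np.pi][: min(n_tips, 2)]
            extras = []
            for j in range(n_tips - len(ends)):
                side = 1 if j % 2 == 0 else -1
                end = 0.0 if (j // 2) % 2 == 0 else np.pi
                extras.append(end + side * rng.uniform(0.75, 1.15))
            r = r * (1.0 + tip_amp * _bump(ends, 0.45))
            if extras:
                r = r + 0.40 * a * _bump(extras, 0.30)
        else:
            # star form: equally spaced tips; each bump's multiplicative
            # amplitude is equalized by the local ellipse radius so all tips
            # protrude by ~tip_amp x mean radius despite the anisotropy
            start = rng.uniform(0.0, 2.0 * np.pi)
            angles = [start + 2.0 * np.pi * i / n_tips for i in range(n_tips)]
            half_w = min(tip_width, 0.8 * np.pi / max(n_tips, 2))
            mean_r = float(r.mean())
            for ang in angles:
                r_loc = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
                amp = tip_amp * mean_r / r_loc
                r = r * (1.0 + amp * _bump([ang], half_w))

    xy = np.c_[r * np.cos(theta), r * np.sin(theta)]
    return Polygon(xy)


def _mrr_geometry(pts: np.ndarray) -> tuple[float, float, float]:
    """(length, width, angle-of-long-axis) of the minimum rotated rectangle."""
    from shapely.geometry import MultiPoint

    rect = MultiPoint(pts).convex_hull.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    edges = np.diff(coords, axis=0, append=coords[:1])[:2]
    lengths = np.linalg.norm(edges, axis=1)
    i_long = int(np.argmax(lengths))
    angle = float(np.arctan2(edges[i_long, 1], edges[i_long, 0]))
    return float(lengths.max()), float(lengths.min()), angle


def _scale_to_elongation(poly: Polygon, target: float, n_iter: int = 4) -> Polygon:
    """Anisotropically rescale so the min-rotated-rect elongation hits target.

    Each pass aligns the current long axis with x, then shrinks/stretches y;
    a few fixed-point passes converge because the rectangle orientation is
    stable once the anisotropy dominates the tip bumps.
    """
    pts = np.asarray(poly.exterior.coords)[:-1]
    for _ in range(n_iter):
        length, width, angle = _mrr_geometry(pts)
        current = 1.0 - width / length
        if abs(current - target) < 5e-4:
            break
        rot = np.array([[np.cos(-angle), -np.sin(-angle)], [np.sin(-angle), np.cos(-angle)]])
        pts = pts @ rot.T
        f = (1.0 - target) / max(1.0 - current, 1e-9)
        pts = pts * np.array([1.0, f])
    return Polygon(pts)


def gen_cell_mask(
    params: ShapeParams,
    rng_seed: int | None = None,
    area: float | None = None,
    elongation: float | None = None,
    n_cusps: int | None = None,
) -> tuple[CellMask, dict]:
    """Render one cell mask; returns (mask, ground_truth).

    Area is drawn Normal(area_mean, area_sd) truncated below at 50 µm²
    (degenerate rasters); elongation Beta(3,3)-scaled within the class band;
    cusp count uniform on the inclusive range. Explicit ``area``/
    ``elongation``/``n_cusps`` override the draws.

    Ground truth records the class label and the target area, elongation
    and rendered tip count of the polygon before rasterization.
    """
    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)

    if area is None:
        area = -1.0
        while area < MIN_AREA_UM2:
            area = rng.normal(params.area_mean, params.area_sd)
    elif area < MIN_AREA_UM2:
        raise ValueError(f"requested area {area:.1f} µm² below the {MIN_AREA_UM2} µm² floor: degenerate shape")
    min_px = 50.0
    if area / params.pixel_size**2 < min_px:
        raise ValueError("requested area smaller than ~50 px² at this pixel size: degenerate shape")

    lo, hi = params.elongation_range
    if elongation is None:
        elongation = lo + (hi - lo) * rng.beta(3.0, 3.0)
    if n_cusps is None:
        n_cusps = int(rng.integers(params.n_cusps_range[0], params.n_cusps_range[1] + 1))

    # strongly elongated shapes are rendered as spindles: both ends are tips
    rendered_tips = max(n_cusps, 2) if (elongation >= 0.56 and n_cusps > 0) else n_cusps

    poly = _star_polygon(rendered_tips, elongation, rng)
    poly = _scale_to_elongation(poly, elongation)
    scale = np.sqrt(area / poly.area)
    pts = np.asarray(poly.exterior.coords)[:-1] * scale  # µm

    angle = rng.uniform(0.0, np.pi)
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    pts = pts @ rot.T

    px = pts / params.pixel_size
    px -= px.min(axis=0) - 3.0
    shape = tuple(np.ceil(px.max(axis=0) + 3.0).astype(int))
    rr, cc = draw.polygon(px[:, 0], px[:, 1], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True

    # very thin spindles can break apart at raster resolution: bridge small
    # gaps, then keep the largest piece as a last resort
    from skimage import measure as skmeasure
    from skimage.morphology import binary_closing, disk

    if skmeasure.label(mask, connectivity=2).max() > 1:
        mask = binary_closing(mask, disk(2))
        lab = skmeasure.label(mask, connectivity=2)
        if lab.max() > 1:
            largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
            mask = lab == largest

    truth = {
        "morph_class": params.morph_class,
        "area_um2": float(area),
        "elongation": float(elongation),
        "n_cusps": int(rendered_tips),
        "n_cusps_requested": int(n_cusps),
        "pixel_size": params.pixel_size,
    }
    cell = CellMask(mask=mask, pixel_size=params.pixel_size, cell_id=f"{params.morph_class}-{rng_seed}")
    return cell, truth


# ---------------------------------------------------------------------------
# nuclei fields
# ---------------------------------------------------------------------------

def gen_nuclei_field(
    params: FieldParams,
    render: bool = False,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    nucleus_sigma_um: float = 3.0,
    background: float = 0.05,
    noise_sd: float = 0.02,
) -> list[dict]:
    """Poisson nucleus placement; optionally renders the DAPI channel.

    Counts are Poisson(density × field_area); positions are placed by
    sequential inhibition with a 15 µm hard core (dart throwing, so the
    drawn count is essentially always realized — at the study densities the
    hard-core packing fraction stays below ~15 %). Each returned dict holds
    ``centroids_um`` (n, 2), ``realized_count``, ``field_area_mm2`` and,
    when ``render`` is set, the DAPI ``image``.
    """
    rng = np.random.default_rng(params.seed)
    side_um = np.sqrt(params.field_area) * 1000.0
    margin = 10.0  # µm beyond the field: edge nuclei are clipped, not absent
    ext_area = ((side_um + 2 * margin) / 1000.0) ** 2  # mm²
    out = []
    for i in range(params.n_fields):
        n_target = rng.poisson(params.density * ext_area)
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n_target and attempts < 200 * max(n_target, 1):
            cand = rng.uniform(-margin, side_um + margin, size=2)
            attempts += 1
            if all(np.linalg.norm(cand - p) >= MIN_NUCLEUS_SEP_UM for p in pts):
                pts.append(cand)
        all_pts = np.array(pts).reshape(-1, 2)
        in_field = np.all((all_pts >= 0.0) & (all_pts < side_um), axis=1)
        centroids = all_pts[in_field]
        rec = {
            "field_id": f"field-{i}",
            "centroids_um": centroids,
            "drawn_count": int(n_target),
            "realized_count": int(len(centroids)),
            "field_area_mm2": params.field_area,
            "pixel_size": pixel_size,
        }
        if render:
            # render on an extended canvas, then crop: out-of-field nuclei
            # contribute clipped blobs exactly as on a real microscope
            pad_px = int(np.ceil(margin / pixel_size))
            n_px = int(round(side_um / pixel_size))
            img = np.zeros((n_px + 2 * pad_px, n_px + 2 * pad_px))
            if len(all_pts):
                ij = np.clip(((all_pts + margin) / pixel_size).astype(int), 0, img.shape[0] - 1)
                img[ij[:, 0], ij[:, 1]] = 1.0
            img = gaussian_filter(img, sigma=nucleus_sigma_um / pixel_size)
            img = img[pad_px:pad_px + n_px, pad_px:pad_px + n_px]
            if img.max() > 0:
                img /= img.max()
            img = background + img + rng.normal(0.0, noise_sd, img.shape)
            rec["image"] = np.clip(img, 0.0, None)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# marker fields
# ---------------------------------------------------------------------------

def _trim_to_count(painted: np.ndarray, target: int, order_key: np.ndarray) -> np.ndarray:
    """Remove excess painted pixels, highest order_key first."""
    excess = int(painted.sum()) - target
    if excess <= 0:
        return painted
    idx = np.argwhere(painted)
    keys = order_key[idx[:, 0], idx[:, 1]]
    drop = idx[np.argsort(keys)[::-1][:excess]]
    painted[drop[:, 0], drop[:, 1]] = False
    return painted


def _paint_punctae(mask: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical punctae (~focal-adhesion sized) painted inside the mask."""
    painted = np.zeros_like(mask)
    # keep puncta centres off the mask rim so blobs are not clipped into
    # sub-detectable fragments
    core = ndi.binary_erosion(mask, iterations=3)
    inner = np.argwhere(core if core.any() else mask)
    guard = 0
    while painted.sum() < target and guard < 100000:
        guard += 1
        cy, cx = inner[rng.integers(len(inner))]
        ry, rx = rng.uniform(1.8, 3.2, size=2)
        ang = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=mask.shape, rotation=ang)
        blob = np.zeros_like(mask)
        blob[rr, cc] = True
        blob &= mask
        new = blob & ~painted
        if painted.sum() + new.sum() > target:
            # final blob: trim it from its rim inward to land exactly
            dist = distance_transform_edt(new)
            add = np.zeros_like(mask)
            need = target - int(painted.sum())
            idx = np.argwhere(new)
            order = np.argsort(dist[idx[:, 0], idx[:, 1]])[::-1]
            sel = idx[order[:need]]
            add[sel[:, 0], sel[:, 1]] = True
            painted |= add
            break
        painted |= new
    return painted


def _paint_filaments(mask: np.ndarray, target: int, rng: np.random.Generator,
                     width_px: int = 3) -> np.ndarray:
    """Straight thick filaments (stress-fiber-like) clipped to the mask."""
    painted = np.zeros_like(mask)
    inner = np.argwhere(mask)
    diag = float(np.hypot(*mask.shape))
    guard = 0
    while painted.sum() < target and guard < 5000:
        guard += 1
        cy, cx = inner[rng.integers(len(inner))]
        ang = rng.uniform(0, np.pi)
        half = rng.uniform(0.15, 0.45) * diag
        y0, x0 = cy - half * np.sin(ang), cx - half * np.cos(ang)
        y1, x1 = cy + half * np.sin(ang), cx + half * np.cos(ang)
        rr, cc = draw.line(*np.clip([int(y0), int(x0)], 0, np.array(mask.shape) - 1),
                           *np.clip([int(y1), int(x1)], 0, np.array(mask.shape) - 1))
        fil = np.zeros_like(mask)
        fil[rr, cc] = True
        if width_px > 1:
            fil = distance_transform_edt(~fil) <= (width_px - 1) / 2.0
        fil &= mask
        new = fil & ~painted
        if painted.sum() + new.sum() > target:
            dist = distance_transform_edt(new)
            need = target - int(painted.sum())
            idx = np.argwhere(new)
            order = np.argsort(dist[idx[:, 0], idx[:, 1]])[::-1]
            sel = idx[order[:need]]
            painted[sel[:, 0], sel[:, 1]] = True
            break
        painted |= new
    return painted


def gen_marker_field(
    cell_mask: CellMask,
    area_fraction: float,
    background_level: float = 0.2,
    noise_sd: float = 0.05,
    rng_seed: int = 0,
    mode: str = "punctae",
    signal: float = 1.0,
    cytosol_actin: float = 0.5,
) -> dict:
    """Two-channel image: actin filling the mask + a marker channel painted
    at exactly ``area_fraction`` of the mask area.

    Modes: ``punctae`` (vinculin-like focal adhesions), ``filament``
    (stress-fiber-like bright fibers on a dimmer cytosolic actin, painted
    into the *actin* channel itself), ``coloc`` (marker structures for
    colocalization-ratio recovery). The true painted-pixel set is returned
    (``truth_painted``); painted count equals round(fraction × mask area)
    exactly, before noise.
    """
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    mask = cell_mask.mask
    target = int(round(area_fraction * mask.sum()))

    if target == 0:
        painted = np.zeros_like(mask)
    elif mode == "punctae":
        painted = _paint_punctae(mask, target, rng)
    elif mode in ("filament", "coloc"):
        painted = _paint_filaments(mask, target, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "filament":
        actin = cytosol_actin * signal * mask + (signal - cytosol_actin * signal) * painted
        marker = actin.copy()
    else:
        actin = signal * mask.astype(float)
        marker = background_level * signal * mask + signal * painted

    if noise_sd > 0:
        actin = actin + rng.normal(0.0, noise_sd * signal, mask.shape)
        marker = marker + rng.normal(0.0, noise_sd * signal, mask.shape)

    return {
        "actin": np.clip(actin, 0.0, None),
        "marker": np.clip(marker, 0.0, None),
        "truth_painted": painted,
        "true_fraction": painted.sum() / mask.sum(),
        "pixel_size": cell_mask.pixel_size,
    }


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

@dataclass
class SyntheticForceCurve:
    z: np.ndarray  # piezo displacement, nm
    d: np.ndarray  # deflection, nm
    k: float  # nN/nm
    R: float  # µm
    nu: float
    truth: dict = field(default_factory=dict)


def hertz_force(delta_nm: np.ndarray, E_kPa: float, R_um: float, nu: float) -> np.ndarray:
    """Spherical-indenter Hertz law, F in nN.

    With E in kPa (≡ nN/µm²), R in µm and δ in µm the prefactor needs no
    unit constant: F = (4/3)·E/(1−ν²)·√R·δ^{3/2}.
    """
    delta_um = np.clip(np.asarray(delta_nm, float), 0.0, None) / 1000.0
    return (4.0 / 3.0) * (E_kPa / (1.0 - nu**2)) * np.sqrt(R_um) * delta_um**1.5


def gen_force_curve(params: CurveParams) -> SyntheticForceCurve:
    """Forward-model an approach force curve.

    The piezo ramps through a flat pre-contact baseline of length
    ``contact_offset`` and then indents to exactly ``max_indentation``
    (trigger). For z beyond contact, indentation solves
    δ + F(δ)/k = z − z0 (piezo motion splits between sample indentation and
    cantilever deflection). Gaussian noise of SD ``noise_sd`` is added to
    force only.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    F_max = hertz_force(p.max_indentation, p.E_true, p.bead_radius, p.poisson_ratio)
    z_max = p.contact_offset + p.max_indentation + F_max / p.spring_constant
    z = np.linspace(0.0, z_max, p.n_points)

    delta = np.zeros_like(z)
    post = z > p.contact_offset
    zz = z[post] - p.contact_offset
    # Newton solve of delta + F(delta)/k = zz in nm (monotone, fast converging)
    dlt = np.clip(zz, 1e-9, None)
    for _ in range(80):
        F = hertz_force(dlt, p.E_true, p.bead_radius, p.poisson_ratio)
        dF = np.where(dlt > 0, 1.5 * F / np.clip(dlt, 1e-12, None), 0.0)
        step = (dlt + F / p.spring_constant - zz) / (1.0 + dF / p.spring_constant)
        dlt = np.clip(dlt - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-10:
            break
    delta[post] = dlt

    F = hertz_force(delta, p.E_true, p.bead_radius, p.poisson_ratio)
    if p.noise_sd > 0:
        F = F + rng.normal(0.0, p.noise_sd, F.shape)
    d = F / p.spring_constant  # deflection in nm

    truth = asdict(p)
    truth["F_max_nN"] = float(F_max)
    return SyntheticForceCurve(z=z, d=d, k=p.spring_constant, R=p.bead_radius,
                               nu=p.poisson_ratio, truth=truth)


# ---------------------------------------------------------------------------
# height profiles
# ---------------------------------------------------------------------------

def gen_height_profile(
    kind: str,
    rms_target: float,
    length: float = 20.0,
    rng_seed: int = 0,
    n_points: int = 2000,
) -> dict:
    """Surface line profile with measured R_rms rescaled exactly to target.

    ``flat``: smoothed Gaussian heights (glass-like). ``fibrous``:
    superposed random filament cross-sections (nanotube-carpet-like).
    Heights are mean-line-leveled and rescaled so the measured RMS equals
    ``rms_target`` (nm) exactly.
    """
    if rms_target < 0:
        raise ValueError("rms_target must be non-negative")
    rng = np.random.default_rng(rng_seed)
    x = np.linspace(0.0, length, n_points)
    if rms_target == 0:
        return {"x_um": x, "h_nm": np.zeros(n_points), "kind": kind}

    if kind == "flat":
        h = gaussian_filter(rng.normal(0.0, 1.0, n_points), sigma=5.0, mode="wrap")
    elif kind == "fibrous":
        h = np.zeros(n_points)
        n_fib = int(length * 3)  # ~3 filaments per µm of scan
        for _ in range(max(n_fib, 5)):
            c = rng.uniform(0.0, length)
            r = rng.uniform(0.08, 0.35)  # filament radius, µm
            dx = x - c
            s = r**2 - dx**2
            h += np.where(s > 0, np.sqrt(np.clip(s, 0, None)), 0.0)
    else:
        raise ValueError("kind must be 'flat' or 'fibrous'")

    # level and rescale so measured RMS hits the target exactly
    coef = np.polyfit(x, h, 1)
    res = h - np.polyval(coef, x)
    rms = np.sqrt(np.mean(res**2))
    h = res * (rms_target / rms)
    return {"x_um": x, "h_nm": h, "kind": kind}


# ---------------------------------------------------------------------------
# analytic helpers (elliptical DOC)
# ---------------------------------------------------------------------------

def ellipse_doc(aspect: float) -> float:
    """Analytic DOC of an ellipse with axis ratio ``aspect`` >= 1."""
    if aspect < 1:
        raise ValueError("aspect must be >= 1")
    a, b = aspect, 1.0
    e2 = 1.0 - (b / a) ** 2
    P = 4.0 * a * ellipe(e2)
    A = np.pi * a * b
    return float(2.0 * np.sqrt(np.pi * A) / P)


def aspect_for_doc(doc: float) -> float:
    """Invert :func:`ellipse_doc`: the aspect ratio whose ellipse has this DOC."""
    if not (0.0 < doc <= 1.0):
        raise ValueError("doc must lie in (0, 1]")
    if doc > ellipse_doc(1.0) - 1e-12:
        return 1.0
    return float(brentq(lambda a: ellipse_doc(a) - doc, 1.0, 200.0))


# ---------------------------------------------------------------------------
# file interfaces (plain-text friendly sidecars; TIFF for images)
# ---------------------------------------------------------------------------

def write_field_tiff(path, channels: dict, pixel_size: float, truth: dict | None = None) -> None:
    """Multi-page TIFF (DAPI, actin, marker order) + JSON ground-truth sidecar."""
    import tifffile

    order = [c for c in ("dapi", "actin", "marker") if c in channels]
    stack = np.stack([np.asarray(channels[c], dtype=np.float32) for c in order])
    tifffile.imwrite(path, stack, metadata={"pixel_size_um": pixel_size, "channels": order})
    if truth is not None:
        side = str(path) + ".json"
        with open(side, "w") as fh:
            json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()}, fh)


def write_force_curve_csv(path, curve: SyntheticForceCurve) -> None:
    """CSV ``z_nm, deflection_nm`` + JSON sidecar with k, R, ν and truth."""
    arr = np.c_[curve.z, curve.d]
    np.savetxt(path, arr, delimiter=",", header="z_nm,deflection_nm", comments="")
    with open(str(path) + ".json", "w") as fh:
        json.dump({"k_nN_per_nm": curve.k, "R_um": curve.R, "nu": curve.nu, **{
            k: v for k, v in curve.truth.items() if not isinstance(v, np.ndarray)}}, fh)
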