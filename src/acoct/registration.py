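"""Geometric mapping of OCT pixels to physical space, surface/focus
detection, bulk-motion correction, resampling and angular fusion.

The mapping model is built from the optical layout: each A-scan column ``u``
is a ray.  The galvo scan translates the ray across the focal plane
(``x_scan = f*tan(theta)``); because the galvo sits a distance ``g != f``
before the lens, the ray direction also changes slightly with ``u``
(``tan(alpha_u) = d/f + (g/f - 1) * tan(theta_u)``), which is the source of
the quadratic image deformation.  The ray refracts at the sample surface and
pixels along it are spaced by one-way optical pathlength.  The focus is the
angle-invariant anchor point of every map.

The same model is used by the simulator to synthesize B-scans, so
registration is by construction the exact inverse of the acquisition
geometry; tests verify the round trip and cross-angle bead alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .beam_optics import BeamGeometry, InvalidGeometryError, in_sample_angle

__all__ = [
    "RegistrationModel",
    "TargetGrid",
    "CompositeImage",
    "AngularImageSet",
    "SurfaceNotFoundError",
    "FocusNotFoundError",
    "detect_surface",
    "estimate_focus",
    "register_image",
    "fuse",
    "correct_bulk_motion",
    "build_models",
]


class SurfaceNotFoundError(RuntimeError):
    """No air-sample transition could be located."""


class FocusNotFoundError(RuntimeError):
    """The focus search landscape is flat (featureless images)."""


@dataclass(frozen=True)
class TargetGrid:
    """Common physical grid: node coordinates in micrometres."""

    x: np.ndarray
    z: np.ndarray

    @classmethod
    def from_extent(cls, x_range, z_range, pitch_x, pitch_z) -> "TargetGrid":
        x = np.arange(x_range[0], x_range[1] + 0.5 * pitch_x, pitch_x)
        z = np.arange(z_range[0], z_range[1] + 0.5 * pitch_z, pitch_z)
        return cls(x=x, z=z)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.z.size, self.x.size)

    def mesh(self):
        return np.meshgrid(self.x, self.z)


@dataclass
class CompositeImage:
    """Registered, fused magnitude image on a physical grid."""

    magnitude: np.ndarray
    contributing_count: np.ndarray
    grid: TargetGrid

    @property
    def valid_mask(self) -> np.ndarray:
        return self.contributing_count > 0


@dataclass
class AngularImageSet:
    """The per-offset averaged magnitude images of one acquisition."""

    images: list
    offsets_d: np.ndarray  # um
    geometry: BeamGeometry
    pixel_pitch_v: float = 1.0
    focus_pixel: tuple[float, float] | None = None


@dataclass(frozen=True)
class RegistrationModel:
    """Pixel (u, v) -> physical (x, z) map for one incidence offset.

    ``mode='full'`` is the geometric model; ``mode='linear'`` truncates it to
    the rotation+translation+scaling baseline (constant ray angle, no
    quadratic scan distortion) used for comparison.
    """

    geometry: BeamGeometry
    offset_d: float                      # um
    focus_pixel_u: float
    focus_physical: tuple[float, float]  # (x_f, z_f) um
    pixel_pitch_u: float
    pixel_pitch_v: float
    surface_row: float                   # image row of the surface at u = u_f
    surface_z0: float = 0.0              # physical surface height at x = 0
    surface_slope: float = 0.0
    surface_rows: np.ndarray | None = None  # optional detected per-column rows
    mode: str = "full"

    # -- per-offset constants -------------------------------------------------
    @property
    def alpha_central(self) -> float:
        return float(np.arctan2(self.offset_d, self.geometry.focal_length))

    @property
    def alpha_s_central(self) -> float:
        return in_sample_angle(self.alpha_central, self.geometry.refractive_index)

    def _surface_z_at(self, x):
        return self.surface_z0 + self.surface_slope * np.asarray(x, dtype=float)

    def _entry_anchor(self) -> float:
        """Lateral entry point of the central ray, chosen so it passes
        exactly through the physical focus."""
        xf, zf = self.focus_physical
        t = np.tan(self.alpha_s_central)
        return (xf - (zf - self.surface_z0) * t) / (1.0 - self.surface_slope * t)

    def column_rays(self, u):
        """Per-column ray parameters.

        Returns ``(x_e, z_e, alpha_u, alpha_s, v_surf)``: surface entry point,
        air and in-sample ray angles, and the image row of the surface.
        """
        g = self.geometry
        u = np.asarray(u, dtype=float)
        xf, zf = self.focus_physical
        f = g.focal_length
        if self.mode == "linear":
            alpha_u = np.full_like(u, self.alpha_central)
        else:
            tan_theta = self.pixel_pitch_u * (u - self.focus_pixel_u) / f
            alpha_u = np.arctan(
                np.tan(self.alpha_central)
                + (g.galvo_lens_distance / f - 1.0) * tan_theta
            )
        alpha_s = np.arcsin(np.sin(alpha_u) / g.refractive_index)

        # air-side ray through the focal-plane scan point, intersected with
        # the surface plane; anchored so the central ray hits the focus
        z_fp_air = self.surface_z0 + (zf - self.surface_z0) / g.refractive_index
        x_scan = xf + self.pixel_pitch_u * (u - self.focus_pixel_u)
        ta = np.tan(alpha_u)
        x_e_raw = (x_scan + (self.surface_z0 - z_fp_air) * ta) / (1.0 - self.surface_slope * ta)
        tac = np.tan(self.alpha_central)
        x_e_raw_c = (xf + (self.surface_z0 - z_fp_air) * tac) / (1.0 - self.surface_slope * tac)
        x_e = x_e_raw + (self._entry_anchor() - x_e_raw_c)
        z_e = self._surface_z_at(x_e)

        if self.surface_rows is not None:
            cols = np.arange(self.surface_rows.size)
            v_surf = np.interp(u, cols, self.surface_rows)
        elif self.mode == "linear":
            v_surf = np.full_like(u, self.surface_row)
        else:
            z_e_c = self._surface_z_at(self._entry_anchor())
            air = (f * (1.0 / np.cos(alpha_u) - 1.0 / np.cos(self.alpha_central))
                   + (z_e - z_e_c) / np.cos(alpha_u))
            v_surf = self.surface_row + air / self.pixel_pitch_v
        return x_e, z_e, alpha_u, alpha_s, v_surf

    @property
    def focus_pixel_v(self) -> float:
        """Row of the focus in this offset's image (nearly offset-invariant)."""
        x_e, z_e, _, alpha_s, v_surf = self.column_rays(np.asarray([self.focus_pixel_u]))
        s_f = (self.focus_physical[1] - z_e[0]) / np.cos(alpha_s[0])
        return float(v_surf[0] + self.geometry.refractive_index * s_f / self.pixel_pitch_v)

    # -- mapping --------------------------------------------------------------
    def forward(self, u, v):
        """Physical ``(x, z)`` of pixel centre(s) ``(u, v)``."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        x_e, z_e, alpha_u, alpha_s, v_surf = self.column_rays(u)
        ri = self.geometry.refractive_index
        opl = self.pixel_pitch_v * (v - v_surf)          # one-way OPL past surface
        below = opl >= 0.0
        s = np.where(below, opl / ri, opl)               # geometric distance
        ang = np.where(below, alpha_s, alpha_u)
        x = x_e + s * np.sin(ang)
        z = z_e + s * np.cos(ang)
        return x, z

    def inverse(self, x, z, n_iter: int = 8):
        """Pixel coordinates ``(u, v)`` of physical point(s); Newton-type
        fixed-point solve of the (mildly nonlinear) column equation."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        u = np.array(self.focus_pixel_u + (
            x - self._entry_anchor()
            - (z - self.surface_z0) * np.tan(self.alpha_s_central)
        ) / self.pixel_pitch_u, dtype=float)
        for _ in range(n_iter):
            x_e, z_e, alpha_u, alpha_s, _ = self.column_rays(u)
            below = z >= z_e
            ang = np.where(below, alpha_s, alpha_u)
            x_pred = x_e + (z - z_e) * np.tan(ang)
            u = u + (x - x_pred) / self.pixel_pitch_u
        x_e, z_e, alpha_u, alpha_s, v_surf = self.column_rays(u)
        below = z >= z_e
        ang = np.where(below, alpha_s, alpha_u)
        s = (z - z_e) / np.cos(ang)
        ri = np.where(below, self.geometry.refractive_index, 1.0)
        v = v_surf + ri * s / self.pixel_pitch_v
        return u, v


def build_models(geometry: BeamGeometry, offsets_d, focus_pixel, surface_row,
                 pixel_pitch_v: float = 1.0, surface_z0: float = 0.0,
                 surface_slope: float = 0.0, mode: str = "full"):
    """One :class:`RegistrationModel` per offset, sharing a focus pixel.

    The physical focus depth is derived from the focus row via the vertical
    (d=0) pathlength relation ``z_f = z0 + p_v*(v_f - v_surf)/RI``.
    """
    u_f, v_f = focus_pixel
    ri = geometry.refractive_index
    z_f = surface_z0 + pixel_pitch_v * (v_f - surface_row) / ri
    return [
        RegistrationModel(
            geometry=geometry, offset_d=float(d), focus_pixel_u=float(u_f),
            focus_physical=(0.0, float(z_f)), pixel_pitch_u=geometry.scan_step,
            pixel_pitch_v=pixel_pitch_v, surface_row=float(surface_row),
            surface_z0=surface_z0, surface_slope=surface_slope, mode=mode,
        )
        for d in offsets_d
    ]


# ---------------------------------------------------------------------------
# surface and focus detection
# ---------------------------------------------------------------------------

def detect_surface(image, smooth_sigma: float = 1.5, min_contrast: float = 3.0):
    """Per-column image row of the air-sample transition.

    Finds, in a lightly smoothed magnitude image, the first depth at which
    intensity exceeds an adaptive threshold between the noise floor and the
    bright percentile; columns without a crossing are interpolated from their
    neighbours and the result is median-smoothed across columns.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    sm = ndimage.gaussian_filter(img, sigma=(smooth_sigma, smooth_sigma))
    # noise floor from the topmost rows (air above the sample)
    n_top = max(3, img.shape[0] // 20)
    floor = np.median(sm[:n_top])
    bright = np.percentile(sm, 99.5)
    if not bright > min_contrast * max(floor, 1e-30):
        raise SurfaceNotFoundError("no air-sample intensity transition found")
    thr = floor + 0.25 * (bright - floor)
    above = sm >= thr
    has = above.any(axis=0)
    if not has.any():
        raise SurfaceNotFoundError("threshold never crossed")
    first = np.where(has, above.argmax(axis=0), np.nan).astype(float)
    cols = np.arange(img.shape[1])
    if np.isnan(first).any():
        good = ~np.isnan(first)
        first = np.interp(cols, cols[good], first[good])
    first = ndimage.median_filter(first, size=7, mode="nearest")
    return ndimage.uniform_filter1d(first, size=5, mode="nearest")


def _running_composites(models, images, grid):
    regs = [register_image(img, m, grid) for img, m in zip(images, models)]
    return regs


def estimate_focus(angular_set: AngularImageSet, *, r_hf_spec=None,
                   coarse_only: bool = False, v_candidates=None):
    """Estimate the focus pixel ``(u_f, v_f)`` shared by all angular images.

    Coarse stage: the surface rows of the different offsets fan out away from
    the focus column, so ``u_f`` is the column where their spread across
    offsets is smallest.  Fine stage: grid search over candidate focus pixels
    maximizing the high-frequency ratio of the trial composite.
    """
    from .metrics import HFMaskSpec, r_hf  # local import; metrics is leaf-level

    if len(angular_set.images) < 3:
        raise ValueError("need at least 3 angular images")
    surfaces = [detect_surface(img) for img in angular_set.images]
    surf = np.stack(surfaces)
    spread = surf.std(axis=0)
    # ignore image borders where detection is least reliable
    n_u = spread.size
    inner = np.arange(n_u // 8, n_u - n_u // 8)
    # surfaces fan out linearly from the focus column, so the squared spread
    # is a parabola: fit it for a sub-pixel column estimate
    coef = np.polyfit(inner, spread[inner] ** 2, 2)
    if coef[0] > 0:
        u_hat = -coef[1] / (2.0 * coef[0])
    else:
        u_hat = inner[np.argmin(spread[inner])]
    u_hat = float(np.clip(u_hat, inner[0], inner[-1]))
    u_f = int(round(u_hat))
    surface_row = float(np.median(surf[:, u_f]))
    n_v = angular_set.images[0].shape[0]
    if coarse_only:
        return (u_f, None), surface_row

    spec = r_hf_spec or HFMaskSpec()
    geometry = angular_set.geometry
    p_v = angular_set.pixel_pitch_v
    ri = geometry.refractive_index

    def score(u_c, v_c):
        models = build_models(geometry, angular_set.offsets_d, (u_c, v_c),
                              surface_row, pixel_pitch_v=p_v)
        zmax = p_v * (n_v - surface_row) / ri
        # exclude the bright surface zone: its rotated ghost copies would
        # otherwise dominate the high-frequency ratio
        grid = TargetGrid.from_extent(
            (-geometry.scan_step * n_u / 2, geometry.scan_step * n_u / 2),
            (10.0 * p_v, zmax), geometry.scan_step, p_v / ri)
        regs = _running_composites(models, angular_set.images, grid)
        comp = fuse(regs)
        m = comp.magnitude.copy()
        m[~comp.valid_mask] = np.mean(m[comp.valid_mask])
        return r_hf(m, spec)

    if v_candidates is None:
        v_candidates = np.arange(int(surface_row) + 14, n_v - 5, 4)
    v_candidates = np.asarray(list(v_candidates))
    scores = np.asarray([score(u_f, v) for v in v_candidates])
    if np.ptp(scores) < 1e-6:
        raise FocusNotFoundError("flat focus-search landscape")
    # the landscape is smooth but shallow: fit a parabola through the scores
    # around the peak instead of trusting single noisy evaluations (the
    # column estimate is common-mode for all angles, so only the row is
    # refined against R_HF)
    i_max = int(np.argmax(scores))
    win = np.abs(v_candidates - v_candidates[i_max]) <= 24
    if win.sum() >= 4:
        c2, c1, _ = np.polyfit(v_candidates[win], scores[win], 2)
        if c2 < 0:
            vertex = -c1 / (2.0 * c2)
            lo, hi = v_candidates[win][0], v_candidates[win][-1]
            v_f = int(round(np.clip(vertex, lo, hi)))
        else:
            v_f = int(v_candidates[i_max])
    else:
        v_f = int(v_candidates[i_max])
    return (int(u_f), v_f), surface_row


# ---------------------------------------------------------------------------
# resampling and fusion
# ---------------------------------------------------------------------------

def register_image(image, model: RegistrationModel, grid: TargetGrid):
    """Resample one angular image onto the physical grid.

    Evaluates the inverse map at every grid node and interpolates
    bilinearly; nodes whose four source neighbours are not all inside the
    image are masked invalid.  Returns ``(registered, valid_mask)``.
    """
    img = np.asarray(image, dtype=float)
    n_v, n_u = img.shape
    xx, zz = grid.mesh()
    u, v = model.inverse(xx, zz)
    if not np.all(np.isfinite(u)) or not np.all(np.isfinite(v)):
        raise InvalidGeometryError("registration model not invertible on extent")
    inside = (u >= 0) & (u <= n_u - 1) & (v >= 0) & (v <= n_v - 1)
    reg = ndimage.map_coordinates(img, [v.ravel(), u.ravel()], order=1,
                                  mode="constant", cval=0.0).reshape(xx.shape)
    reg[~inside] = 0.0
    return reg, inside


def fuse(registered) -> CompositeImage:
    """Per-pixel mean of magnitudes over the contributing (valid) angles."""
    if len(registered) == 0:
        raise ValueError("need at least one registered image")
    imgs = np.stack([r[0] for r in registered])
    masks = np.stack([r[1] for r in registered])
    count = masks.sum(axis=0)
    total = (imgs * masks).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    n_z, n_x = mean.shape
    grid = TargetGrid(x=np.arange(n_x, dtype=float), z=np.arange(n_z, dtype=float))
    return CompositeImage(magnitude=mean, contributing_count=count, grid=grid)


def correct_bulk_motion(images, max_shift: int = 10):
    """Remove rigid vertical sample shifts between angular acquisitions.

    The shift of each image is the (rounded) median offset of its detected
    surface from the across-image median surface; images are translated back
    by whole pixels.  Returns ``(aligned_images, shifts)``.
    """
    import warnings

    surfaces = [detect_surface(img) for img in images]
    # sample the surface around the centre columns: away from there the
    # angular surfaces legitimately fan apart (path-length sec term)
    n_u = surfaces[0].size
    centre = slice(2 * n_u // 5, 3 * n_u // 5)
    rows = [np.median(s[centre]) for s in surfaces]
    med = np.median(rows)
    shifts = [int(np.round(r - med)) for r in rows]
    aligned = []
    for img, sh in zip(images, shifts):
        if abs(sh) > max_shift:
            warnings.warn(f"bulk-motion shift {sh} px exceeds bound {max_shift}")
        if sh == 0:
            aligned.append(np.asarray(img).copy())
        else:
            out = np.zeros_like(np.asarray(img))
            if sh > 0:
                out[:-sh] = img[sh:]
            else:
                out[-sh:] = img[:sh]
            aligned.append(out)
    return aligned, shifts
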