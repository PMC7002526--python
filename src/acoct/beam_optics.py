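"""Gaussian-beam illumination model and system geometry.

Internal units are micrometres for lengths and radians for angles.  The
public helpers :func:`incident_angle` and the CLI accept the instrument's
native units (millimetres, degrees) and convert at the boundary.

Coordinate convention: ``x`` is the lateral scan direction, ``z`` is depth
(positive downward), with the origin at the nominal sample surface directly
below the lens axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "BeamGeometry",
    "IncidenceConfig",
    "incident_angle",
    "in_sample_angle",
    "focal_spot_radius",
    "gaussian_field",
    "round_trip_pathlength",
    "MM",
]

#: micrometres per millimetre, for converting instrument-native inputs
MM = 1000.0


class InvalidGeometryError(ValueError):
    """Raised when optical-system parameters are non-physical."""


def focal_spot_radius(wavelength: float, focal_length: float, beam_diameter: float) -> float:
    """1/e^2 focal spot radius ``2*lambda*f / (pi*D_B)``.

    All three arguments share one length unit; the result is in that unit.
    """
    if wavelength < 0 or focal_length <= 0 or beam_diameter <= 0:
        raise InvalidGeometryError(
            "wavelength must be >= 0 and focal_length, beam_diameter > 0"
        )
    return 2.0 * wavelength * focal_length / (np.pi * beam_diameter)


@dataclass(frozen=True)
class BeamGeometry:
    """Optical system constants (lengths in micrometres).

    Defaults match a 920 nm spectral-domain system with a 36 mm objective,
    5.4 mm collimated beam, galvo scanner 59 mm before the lens and a
    0.976 um scan step.
    """

    wavelength: float = 0.92
    beam_diameter: float = 5.4 * MM
    focal_length: float = 36.0 * MM
    galvo_lens_distance: float = 59.0 * MM
    refractive_index: float = 1.34
    axial_resolution: float = 2.0
    scan_step: float = 0.976
    waist_radius: float | None = None

    def __post_init__(self) -> None:
        for name in ("wavelength", "beam_diameter", "focal_length",
                     "galvo_lens_distance", "axial_resolution", "scan_step"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        if self.refractive_index < 1.0:
            raise InvalidGeometryError("refractive_index must be >= 1")
        if self.waist_radius is None:
            object.__setattr__(
                self, "waist_radius",
                focal_spot_radius(self.wavelength, self.focal_length, self.beam_diameter),
            )
        elif self.waist_radius <= 0:
            raise InvalidGeometryError("waist_radius must be positive")

    @property
    def wavenumber(self) -> float:
        """Vacuum wavenumber ``2*pi/lambda`` (rad/um)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def focal_spot_radius(self) -> float:
        """1/e^2 beam radius at focus (um)."""
        return focal_spot_radius(self.wavelength, self.focal_length, self.beam_diameter)

    @property
    def rayleigh_range(self) -> float:
        """Rayleigh range ``pi*w0^2/lambda`` in air (um)."""
        return np.pi * self.waist_radius**2 / self.wavelength

    def rayleigh_range_medium(self, refractive_index: float | None = None) -> float:
        """Rayleigh range inside a medium (wavelength shortened by RI)."""
        ri = self.refractive_index if refractive_index is None else refractive_index
        return self.rayleigh_range * ri


def incident_angle(offset_d: float, focal_length: float) -> float:
    """Incident angle ``arctan(d/f)`` in *degrees* for a scanner offset.

    ``offset_d`` and ``focal_length`` share a unit (typically mm).  Odd in
    ``offset_d``.
    """
    if focal_length <= 0:
        raise InvalidGeometryError("focal_length must be positive")
    return float(np.degrees(np.arctan2(offset_d, focal_length)))


def in_sample_angle(alpha: float, refractive_index: float) -> float:
    """Refracted propagation angle inside the sample (radians in, radians out).

    Snell's law at a horizontal interface: ``asin(sin(alpha)/RI)``.
    """
    if refractive_index < 1.0:
        raise InvalidGeometryError("refractive_index must be >= 1")
    return float(np.arcsin(np.sin(alpha) / refractive_index))


@dataclass(frozen=True)
class IncidenceConfig:
    """One angular acquisition: scanner offset and derived angles.

    ``offset_d`` is in micrometres.  ``focus_physical`` is the nominal
    in-sample focus ``(x, z)`` in micrometres; it is the angle-independent
    reference point of the whole method.
    """

    offset_d: float
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    focus_physical: tuple[float, float] = (0.0, 300.0)

    @property
    def incident_angle_rad(self) -> float:
        return float(np.arctan2(self.offset_d, self.geometry.focal_length))

    @property
    def incident_angle_deg(self) -> float:
        return float(np.degrees(self.incident_angle_rad))

    @property
    def in_sample_angle_rad(self) -> float:
        return in_sample_angle(self.incident_angle_rad, self.geometry.refractive_index)


def _rotated_coords(x, z, inc: IncidenceConfig):
    """Coordinates (lateral x', axial y') about the focus, rotated by the
    in-sample propagation angle."""
    a = inc.in_sample_angle_rad
    xf, zf = inc.focus_physical
    dx = np.asarray(x, dtype=float) - xf
    dz = np.asarray(z, dtype=float) - zf
    x_p = dx * np.cos(a) - dz * np.sin(a)
    y_p = dx * np.sin(a) + dz * np.cos(a)
    return x_p, y_p


def _curvature_term(x_p, y_p, rayleigh):
    """Quadratic wavefront sag ``x'^2 / (2 y' + 2 R_y^2/y')``; 0 on the
    focal plane (the curvature radius diverges there)."""
    y = np.asarray(y_p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 2.0 * y + 2.0 * rayleigh**2 / y
        sag = np.where(y == 0.0, 0.0, np.asarray(x_p) ** 2 / np.where(y == 0.0, 1.0, denom))
    return sag


def gaussian_field(x, z, geometry: BeamGeometry, inc: IncidenceConfig,
                   refractive_index: float | None = None):
    """Complex focused-Gaussian field at physical point(s) ``(x, z)``.

    The beam propagates at the in-sample angle of ``inc`` with its waist at
    ``inc.focus_physical``; the medium shortens the wavelength by RI.
    Amplitude is 1 at the focus.  Accepts scalars or broadcastable arrays.
    """
    ri = geometry.refractive_index if refractive_index is None else refractive_index
    x_p, y_p = _rotated_coords(x, z, inc)
    w0 = geometry.waist_radius
    ry = geometry.rayleigh_range_medium(ri)
    k_med = geometry.wavenumber * ri
    w_b = w0 * np.sqrt(1.0 + (y_p / ry) ** 2)
    amp = (w0 / w_b) * np.exp(-(x_p**2) / w_b**2)
    sag = _curvature_term(x_p, y_p, ry)
    phase = -k_med * y_p - k_med * sag + np.arctan2(y_p, ry)
    out = amp * np.exp(1j * phase)
    if np.ndim(out) == 0:
        return complex(out)
    return out


def round_trip_pathlength(x, z, geometry: BeamGeometry, inc: IncidenceConfig,
                          surface_z: float = 0.0, include_curvature: bool = True,
                          refractive_index: float | None = None):
    """Round-trip optical pathlength to ``(x, z)``, referenced to the beam
    axis' surface crossing (returns 0 there).

    The confocal gate doubles the one-way path.  Below the surface the
    geometric path is scaled by RI; the quadratic wavefront sag of the
    focused beam is included unless ``include_curvature`` is False, so that
    off-axis points at equal depth sit on a longer path.
    """
    ri = geometry.refractive_index if refractive_index is None else refractive_index
    x_p, y_p = _rotated_coords(x, z, inc)
    a = inc.in_sample_angle_rad
    _, zf = inc.focus_physical
    # axial position of the surface crossing along the beam, relative to focus
    y_surf = (surface_z - zf) / np.cos(a)
    below = y_p >= y_surf
    scale = np.where(below, ri, 1.0)
    opl = scale * (np.asarray(y_p) - y_surf)
    if include_curvature:
        ry = geometry.rayleigh_range_medium(ri)
        opl = opl + ri * _curvature_term(x_p, y_p, ry)
    out = 2.0 * opl
    if np.ndim(out) == 0:
        return float(out)
    return out
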