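"""Phantom generation and physics-based synthesis of angle-coded complex
B-scan stacks.

Each column of a simulated B-scan is one ray of the registration geometry;
scatterer contributions are weighted by the focused-Gaussian lateral
envelope, gated axially by the coherence length, and carry the round-trip
phase ``exp(-i*2k*OPL)`` including the defocus wavefront sag.  Speckle
therefore arises from genuine sub-resolution scatterer interference, and
registration of the synthetic data is exactly invertible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .beam_optics import BeamGeometry, IncidenceConfig
from .registration import RegistrationModel

__all__ = [
    "Phantom",
    "ComplexBScanStack",
    "make_bead_phantom",
    "make_speckle_phantom",
    "simulation_model",
    "simulate_bscan",
    "simulate_angular_set",
    "simulate_spectral_interferogram",
    "reconstruct_ascans",
    "forward_map",
]

UM3_PER_ML = 1.0e12  # 1 ml = 1 cm^3


@dataclass
class Phantom:
    """Point scatterers in the x-z plane plus a (possibly tilted) surface.

    ``scatterers`` is an (N, 3) array of ``(x_um, z_um, amplitude)``.
    """

    scatterers: np.ndarray
    extent: tuple[tuple[float, float], tuple[float, float]]
    refractive_index: float = 1.34
    surface_z0: float = 0.0
    surface_slope: float = 0.0

    def __post_init__(self) -> None:
        sc = np.asarray(self.scatterers, dtype=float).reshape(-1, 3)
        if sc.size and np.any(sc[:, 2] < 0):
            raise ValueError("scatterer amplitudes must be non-negative")
        self.scatterers = sc

    def surface_z(self, x):
        return self.surface_z0 + self.surface_slope * np.asarray(x, dtype=float)

    def with_surface_line(self, amplitude: float = 1.0, spacing: float = 0.9,
                          depth_below: float = 0.5) -> "Phantom":
        """Add a dense line of scatterers just under the surface so the
        air-sample transition is visible in every angular image."""
        (x0, x1), _ = self.extent
        xs = np.arange(x0, x1, spacing)
        line = np.column_stack([xs, self.surface_z(xs) + depth_below,
                                np.full(xs.size, amplitude)])
        sc = np.vstack([self.scatterers, line]) if self.scatterers.size else line
        return Phantom(sc, self.extent, self.refractive_index,
                       self.surface_z0, self.surface_slope)

    def shifted(self, dz: float) -> "Phantom":
        """Rigid vertical shift (bulk motion) of scatterers and surface."""
        sc = self.scatterers.copy()
        if sc.size:
            sc[:, 1] += dz
        return Phantom(sc, self.extent, self.refractive_index,
                       self.surface_z0 + dz, self.surface_slope)


@dataclass
class ComplexBScanStack:
    """Repeated complex B-scans at one scanner offset.

    ``data`` has shape (repeats, depth v, scan u); the v axis is one-way
    optical pathlength in units of ``pixel_pitch_v``.
    """

    data: np.ndarray
    pixel_pitch_u: float
    pixel_pitch_v: float
    offset_d: float                  # um
    geometry: BeamGeometry
    seed: int | None = None
    focus_pixel: tuple[float, float] | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (repeats, n_v, n_u)")
        if self.pixel_pitch_u <= 0 or self.pixel_pitch_v <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    def magnitude_mean(self) -> np.ndarray:
        """Angular image: mean of absolute values over repeats."""
        return np.abs(self.data).mean(axis=0)


def make_bead_phantom(density_per_ml: float, extent, slab_thickness: float = 2.0,
                      amplitude_law=None, seed: int | None = None,
                      refractive_index: float = 1.34,
                      margin: float = 5.0) -> Phantom:
    """Poisson-sampled bead phantom mimicking a dilute microsphere slab.

    The expected count is ``density * area * slab_thickness`` (density in
    beads/ml, lengths in um).  Beads are kept ``margin`` below the surface.
    """
    if density_per_ml < 0:
        raise ValueError("density must be non-negative")
    (x0, x1), (z0, z1) = extent
    rng = np.random.default_rng(seed)
    volume = (x1 - x0) * (z1 - z0) * slab_thickness  # um^3
    n = rng.poisson(density_per_ml * volume / UM3_PER_ML)
    x = rng.uniform(x0, x1, n)
    z = rng.uniform(max(z0, margin), z1, n)
    amp = np.ones(n) if amplitude_law is None else np.asarray(amplitude_law(rng, n))
    return Phantom(np.column_stack([x, z, amp]), extent,
                   refractive_index=refractive_index)


def make_speckle_phantom(scatterers_per_voxel: float, extent,
                         seed: int | None = None, voxel_area: float = 8.0,
                         refractive_index: float = 1.34,
                         margin: float = 3.0) -> Phantom:
    """Dense random sub-resolution scatterers producing fully developed
    speckle (many independent phasors per ~8 um^2 detection voxel)."""
    if scatterers_per_voxel < 0:
        raise ValueError("scatterers_per_voxel must be non-negative")
    (x0, x1), (z0, z1) = extent
    rng = np.random.default_rng(seed)
    area = (x1 - x0) * (z1 - z0)
    n = rng.poisson(scatterers_per_voxel * area / voxel_area)
    x = rng.uniform(x0, x1, n)
    z = rng.uniform(max(z0, margin), z1, n)
    amp = rng.uniform(0.5, 1.0, n)
    return Phantom(np.column_stack([x, z, amp]), extent,
                   refractive_index=refractive_index)


def simulation_model(phantom: Phantom, geometry: BeamGeometry, offset_d: float,
                     n_u: int, focus_depth: float, pixel_pitch_v: float = 1.0,
                     surface_row: float = 30.0) -> RegistrationModel:
    """The ground-truth pixel-to-space model used to synthesize a B-scan."""
    return RegistrationModel(
        geometry=geometry, offset_d=offset_d, focus_pixel_u=(n_u - 1) / 2.0,
        focus_physical=(0.0, focus_depth), pixel_pitch_u=geometry.scan_step,
        pixel_pitch_v=pixel_pitch_v, surface_row=surface_row,
        surface_z0=phantom.surface_z0, surface_slope=phantom.surface_slope,
    )


def simulate_bscan(phantom: Phantom, geometry: BeamGeometry, offset_d: float,
                   n_u: int = 256, n_v: int = 256, focus_depth: float = 120.0,
                   pixel_pitch_v: float = 1.0, surface_row: float = 30.0,
                   noise_level: float = 0.0, repeats: int = 1,
                   seed: int | None = None) -> ComplexBScanStack:
    """Synthesize a complex B-scan stack for one scanner offset.

    For every column the scatterers near the ray contribute
    ``A_n * envelope * gate * exp(-i*2k*OPL_n)``; circular complex Gaussian
    noise of standard deviation ``noise_level`` per quadrature is added
    independently per repeat.
    """
    model = simulation_model(phantom, geometry, offset_d, n_u, focus_depth,
                             pixel_pitch_v, surface_row)
    ri = phantom.refractive_index
    if abs(ri - geometry.refractive_index) > 1e-12:
        geometry = BeamGeometry(**{**geometry.__dict__, "refractive_index": ri,
                                   "waist_radius": geometry.waist_radius})
        model = simulation_model(phantom, geometry, offset_d, n_u, focus_depth,
                                 pixel_pitch_v, surface_row)
    sc = phantom.scatterers
    img = np.zeros((n_v, n_u), dtype=complex)
    if sc.size:
        (x0e, x1e), _ = phantom.extent
        w0 = geometry.waist_radius
        ry = geometry.rayleigh_range_medium()
        k = geometry.wavenumber
        sigma_opl = geometry.axial_resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_v = sigma_opl / pixel_pitch_v
        win = max(2, int(np.ceil(4.0 * sigma_v)))
        cols = np.arange(n_u, dtype=float)
        x_e, z_e, _, alpha_s, v_surf = model.column_rays(cols)
        if x_e.min() < x0e or x_e.max() > x1e:
            warnings.warn("scan positions extend beyond the phantom extent; "
                          "outside columns will be empty")
        sin_a, cos_a = np.sin(alpha_s), np.cos(alpha_s)
        xs, zs, amps = sc[:, 0], sc[:, 1], sc[:, 2]
        s_focus = (focus_depth - z_e) / cos_a
        # widest possible beam radius over the imaged depth, for pre-filtering
        y_max = max(abs(n_v * pixel_pitch_v / ri), focus_depth) + 10.0
        w_max = w0 * np.sqrt(1.0 + (y_max / ry) ** 2)
        rows = np.arange(n_v)
        for j in range(n_u):
            dx = xs - x_e[j]
            dz = zs - z_e[j]
            s = dx * sin_a[j] + dz * cos_a[j]
            x_lat = dx * cos_a[j] - dz * sin_a[j]
            near = (np.abs(x_lat) < 3.0 * w_max) & (s > 0)
            if not near.any():
                continue
            s_n, x_n, a_n = s[near], x_lat[near], amps[near]
            y_n = s_n - s_focus[j]
            w_b = w0 * np.sqrt(1.0 + (y_n / ry) ** 2)
            env = (w0 / w_b) * np.exp(-(x_n**2) / w_b**2)
            keep = env > 1e-4
            if not keep.any():
                continue
            s_n, x_n, y_n, a_n, env, w_b = (arr[keep] for arr in
                                            (s_n, x_n, y_n, a_n, env, w_b))
            with np.errstate(divide="ignore"):
                sag = np.where(y_n == 0.0, 0.0,
                               x_n**2 / (2.0 * y_n + 2.0 * ry**2 / np.where(y_n == 0, 1, y_n)))
            opl = pixel_pitch_v * v_surf[j] + ri * (s_n + sag)
            c_n = a_n * env * np.exp(-1j * 2.0 * k * opl)
            v_n = v_surf[j] + ri * s_n / pixel_pitch_v
            base = np.round(v_n).astype(int)
            for w in range(-win, win + 1):
                rows_w = base + w
                ok = (rows_w >= 0) & (rows_w < n_v)
                if not ok.any():
                    continue
                gate = np.exp(-((rows_w[ok] - v_n[ok]) ** 2) / (2.0 * sigma_v**2))
                np.add.at(img[:, j], rows_w[ok], c_n[ok] * gate)
    rng = np.random.default_rng(seed)
    data = np.broadcast_to(img, (repeats, n_v, n_u)).copy()
    if noise_level > 0:
        data = data + noise_level * (
            rng.standard_normal((repeats, n_v, n_u))
            + 1j * rng.standard_normal((repeats, n_v, n_u)))
    return ComplexBScanStack(
        data=data, pixel_pitch_u=geometry.scan_step, pixel_pitch_v=pixel_pitch_v,
        offset_d=offset_d, geometry=geometry, seed=seed,
        focus_pixel=((n_u - 1) / 2.0, model.focus_pixel_v),
        attrs={"focus_depth": focus_depth, "surface_row": surface_row,
               "noise_level": noise_level},
    )


def simulate_angular_set(phantom: Phantom, geometry: BeamGeometry, offsets_d,
                         seed: int | None = None, **kwargs):
    """Simulate one stack per scanner offset (independent noise seeds)."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(list(offsets_d)))
    return [simulate_bscan(phantom, geometry, float(d), seed=int(s), **kwargs)
            for d, s in zip(offsets_d, seeds)]


def forward_map(u, v, stack_or_model, *args, **kwargs):
    """Physical coordinates of pixel centres of a simulated stack.

    Accepts either a :class:`ComplexBScanStack` produced by
    :func:`simulate_bscan` (using its stored ground-truth geometry) or a
    :class:`RegistrationModel` directly.
    """
    if isinstance(stack_or_model, RegistrationModel):
        return stack_or_model.forward(u, v)
    st = stack_or_model
    model = RegistrationModel(
        geometry=st.geometry, offset_d=st.offset_d,
        focus_pixel_u=st.focus_pixel[0],
        focus_physical=(0.0, st.attrs["focus_depth"]),
        pixel_pitch_u=st.pixel_pitch_u, pixel_pitch_v=st.pixel_pitch_v,
        surface_row=st.attrs["surface_row"],
    )
    return model.forward(u, v)


# ---------------------------------------------------------------------------
# spectral-domain synthesis (exercises the FFT preparation step end to end)
# ---------------------------------------------------------------------------

def simulate_spectral_interferogram(phantom: Phantom, geometry: BeamGeometry,
                                    offset_d: float, n_u: int = 64,
                                    n_pixels: int = 2048,
                                    focus_depth: float = 120.0,
                                    pixel_pitch_v: float = 1.0,
                                    surface_row: float = 30.0,
                                    noise_level: float = 0.0,
                                    seed: int | None = None):
    """Per-A-scan real spectral fringes whose Fourier transform recovers the
    depth-encoded complex A-scans.

    The spectrometer k-grid spacing is chosen so one depth pixel equals
    ``pixel_pitch_v`` of optical pathlength; the Gaussian source envelope
    width reproduces the axial resolution.  Returns an (n_u, n_pixels) real
    array.
    """
    model = simulation_model(phantom, geometry, offset_d, n_u, focus_depth,
                             pixel_pitch_v, surface_row)
    ri = phantom.refractive_index
    w0 = geometry.waist_radius
    ry = geometry.rayleigh_range_medium(ri)
    k_c = geometry.wavenumber
    dk = np.pi / (n_pixels * pixel_pitch_v)
    j = np.arange(n_pixels)
    k_grid = k_c + dk * (j - n_pixels / 2)
    sigma_k = np.sqrt(2.0 * np.log(2.0)) / geometry.axial_resolution
    envelope = np.exp(-((k_grid - k_c) ** 2) / (2.0 * sigma_k**2))

    cols = np.arange(n_u, dtype=float)
    x_e, z_e, _, alpha_s, v_surf = model.column_rays(cols)
    sin_a, cos_a = np.sin(alpha_s), np.cos(alpha_s)
    s_focus = (focus_depth - z_e) / cos_a
    sc = phantom.scatterers
    spectra = np.zeros((n_u, n_pixels))
    rng = np.random.default_rng(seed)
    for jcol in range(n_u):
        if sc.size:
            dx = sc[:, 0] - x_e[jcol]
            dz = sc[:, 1] - z_e[jcol]
            s = dx * sin_a[jcol] + dz * cos_a[jcol]
            x_lat = dx * cos_a[jcol] - dz * sin_a[jcol]
            y = s - s_focus[jcol]
            w_b = w0 * np.sqrt(1.0 + (y / ry) ** 2)
            env = (w0 / w_b) * np.exp(-(x_lat**2) / w_b**2)
            keep = (env > 1e-4) & (s > 0)
            if keep.any():
                with np.errstate(divide="ignore"):
                    sag = np.where(y == 0.0, 0.0,
                                   x_lat**2 / (2.0 * y + 2.0 * ry**2 / np.where(y == 0, 1, y)))
                opl = pixel_pitch_v * v_surf[jcol] + ri * (s + sag)
                amp = (sc[:, 2] * env)[keep]
                fringe = amp[:, None] * envelope[None, :] * np.exp(
                    -1j * 2.0 * k_grid[None, :] * opl[keep, None])
                spectra[jcol] = fringe.real.sum(axis=0)
        if noise_level > 0:
            spectra[jcol] += noise_level * rng.standard_normal(n_pixels)
    return spectra


def reconstruct_ascans(spectra, geometry: BeamGeometry, n_v: int = 256,
                       pixel_pitch_v: float = 1.0) -> np.ndarray:
    """Recover complex A-scans from spectral fringes (the PREPARATION step).

    Returns an (n_v, n_u) complex image; the conjugate (negative-pathlength)
    image falls outside the retained depth window.
    """
    spectra = np.asarray(spectra, dtype=float)
    n_u, n_pixels = spectra.shape
    dk = np.pi / (n_pixels * pixel_pitch_v)
    j = np.arange(n_pixels)
    sigma_k = np.sqrt(2.0 * np.log(2.0)) / geometry.axial_resolution
    envelope = np.exp(-((j - n_pixels / 2) * dk) ** 2 / (2.0 * sigma_k**2))
    norm = envelope.sum() / 2.0
    # a_m = (1/norm) * sum_j S_j exp(+i*2*dk*(j - n/2)*L_m), L_m = m*p_v
    a = n_pixels * np.fft.ifft(spectra, axis=1)
    m = np.arange(n_v)
    shift = np.exp(-1j * np.pi * m)  # accounts for the (j - n/2) k-grid origin
    img = (a[:, :n_v] * shift[None, :]) / norm
    return img.T.copy()
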