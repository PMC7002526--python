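"""Analytic and Monte-Carlo model of speckle formation in one voxel and its
suppression by averaging over incident-angle-induced phase shifts.

Two sub-resolution scatterers interfering within one detection voxel produce
the amplitude ``sqrt(2)*A1*sqrt(1 + cos(dP))``; sweeping the phase difference
``dP`` uniformly over one period stabilises the voxel at ``(4/pi)*A1`` with
the spread collapsing from ``A1*sqrt(2 - 16/pi^2)`` (~0.62 A1) towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelScatterers",
    "two_scatterer_amplitude",
    "phase_shift_from_angle",
    "min_separation_for_full_period",
    "max_offset_travel_ratio",
    "phase_averaged_mean",
    "phase_averaged_std",
    "multi_scatterer_signal",
    "angle_ensemble_mean",
]


@dataclass(frozen=True)
class VoxelScatterers:
    """Scatterers sharing one voxel, referenced to the first scatterer.

    ``distances`` are signed: positive when a positive angle change decreases
    the phase difference to the reference scatterer.
    """

    amplitudes: np.ndarray
    initial_phase_diffs: np.ndarray = field(default=None)  # type: ignore[assignment]
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if amps.size < 1:
            raise ValueError("need at least one scatterer")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        phases = (np.zeros_like(amps) if self.initial_phase_diffs is None
                  else np.atleast_1d(np.asarray(self.initial_phase_diffs, dtype=float)))
        dists = (np.zeros_like(amps) if self.distances is None
                 else np.atleast_1d(np.asarray(self.distances, dtype=float)))
        if not (amps.shape == phases.shape == dists.shape):
            raise ValueError("amplitudes, phases and distances must have equal length")
        if phases[0] != 0.0 or dists[0] != 0.0:
            raise ValueError("reference scatterer must have zero phase and distance")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "initial_phase_diffs", phases)
        object.__setattr__(self, "distances", dists)

    @property
    def n(self) -> int:
        return int(self.amplitudes.size)


def two_scatterer_amplitude(phase_diff, a1=1.0):
    """``sqrt(2)*A1*sqrt(1 + cos(dP))`` — amplitude of two equal scatterers.

    Ranges over [0, 2*A1] and is 2*pi-periodic in ``phase_diff``.
    """
    a1 = np.asarray(a1, dtype=float)
    if np.any(a1 < 0):
        raise ValueError("a1 must be non-negative")
    val = np.sqrt(2.0) * a1 * np.sqrt(np.maximum(1.0 + np.cos(phase_diff), 0.0))
    if np.ndim(val) == 0:
        return float(val)
    return val


def phase_shift_from_angle(delta_alpha, separation, wavelength, refractive_index=1.0):
    """Round-trip phase shift ``2 * (2*pi/lambda) * RI * D12 * dAlpha``
    induced on a scatterer pair by an incident-angle change (radians)."""
    if np.any(np.asarray(wavelength) <= 0):
        raise ValueError("wavelength must be positive")
    k = 2.0 * np.pi / np.asarray(wavelength, dtype=float)
    val = 2.0 * k * refractive_index * np.asarray(separation) * np.asarray(delta_alpha)
    if np.ndim(val) == 0:
        return float(val)
    return val


def min_separation_for_full_period(delta_alpha, wavelength, refractive_index=1.0):
    """Smallest scatterer separation for which the available angle change
    sweeps a full 2*pi phase shift: ``lambda / (2 * RI * dAlpha)``."""
    if delta_alpha == 0:
        raise ValueError("delta_alpha must be nonzero")
    return float(wavelength / (2.0 * refractive_index * abs(delta_alpha)))


def max_offset_travel_ratio() -> float:
    """Maximum scanner travel as a multiple of the beam diameter.

    Requiring a 2*pi shift across the focal spot radius ``2*lambda*f/(pi*D_B)``
    with ``dAlpha = dd/(f*RI)`` gives ``dd_max = (pi/4) * D_B``, independent of
    wavelength and focal length.
    """
    # 2*(2pi/lam)*RI*R_S*dd/(f*RI) = 2pi  with  R_S = 2*lam*f/(pi*D_B)
    return float(np.pi / 4.0)


def phase_averaged_mean(a1=1.0):
    """Uniform-phase average of the two-scatterer amplitude: ``(4/pi)*A1``."""
    if np.any(np.asarray(a1) < 0):
        raise ValueError("a1 must be non-negative")
    val = (4.0 / np.pi) * np.asarray(a1, dtype=float)
    return float(val) if np.ndim(val) == 0 else val


def phase_averaged_std(a1=1.0):
    """Standard deviation of the un-averaged two-scatterer amplitude under a
    uniform phase difference: ``A1*sqrt(2 - 16/pi^2)`` (~0.6156 A1)."""
    if np.any(np.asarray(a1) < 0):
        raise ValueError("a1 must be non-negative")
    val = np.sqrt(2.0 - 16.0 / np.pi**2) * np.asarray(a1, dtype=float)
    return float(val) if np.ndim(val) == 0 else val


def multi_scatterer_signal(voxel: VoxelScatterers, delta_alpha,
                           wavelength, refractive_index=1.0):
    """|coherent sum| of all scatterers in a voxel at angle change(s)
    ``delta_alpha``: ``|sum A_n exp(-i*2*dP_n) exp(-i*2*k*RI*D_n*dAlpha)|``."""
    da = np.asarray(delta_alpha, dtype=float)
    k = 2.0 * np.pi / wavelength
    phases = (2.0 * voxel.initial_phase_diffs
              + 2.0 * k * refractive_index * np.multiply.outer(da, voxel.distances))
    s = np.sum(voxel.amplitudes * np.exp(-1j * phases), axis=-1)
    out = np.abs(s)
    return float(out) if np.ndim(out) == 0 else out


def angle_ensemble_mean(voxel: VoxelScatterers, angle_changes,
                        wavelength, refractive_index=1.0) -> float:
    """Mean voxel amplitude over a finite set of incident-angle changes."""
    angles = np.atleast_1d(np.asarray(angle_changes, dtype=float))
    if angles.size == 0:
        raise ValueError("angle_changes must be non-empty")
    return float(np.mean(multi_scatterer_signal(voxel, angles, wavelength, refractive_index)))
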