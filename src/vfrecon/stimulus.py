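"""Combined wedge-and-ring retinotopic mapping stimulus.

The mapping stimulus is a rotating 18-deg wedge presented simultaneously
with an expanding/contracting ring inside a 6.5-deg-radius field.  One
scan holds two 120 s cycles (the aperture advancing one step per 2 s TR)
followed by a 48 s blank, i.e. 288 s.  Only the binary aperture matters
for receptive-field modelling; the checkerboard carrier is not modelled.

Coordinates are degrees of visual angle: x positive rightward, y positive
upward, origin at fixation.  "3 o'clock" is polar angle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusDesign",
    "StimulusAperture",
    "build_wedge_ring",
    "squeeze_vertical",
    "time_average_map",
]


class StimulusConfigError(ValueError):
    """Raised for inconsistent stimulus design parameters."""


@dataclass(frozen=True)
class StimulusDesign:
    """Timing and geometry of one wedge-and-ring mapping scan.

    Parameters
    ----------
    cycle_s : duration of one wedge revolution / ring sweep (s).
    n_cycles : stimulated cycles per scan.
    blank_s : trailing blank period (s).
    frame_duration_s : aperture step = TR (s).
    field_radius_deg : stimulated field radius (deg).
    wedge_width_deg : angular width of the wedge (deg).
    direction : ``"cw_expand"`` (clockwise wedge, expanding ring) or
        ``"ccw_contract"``; both start the wedge at 3 o'clock.
    ring_r0_deg : offset of the logarithmic eccentricity spacing; ring
        borders are equally spaced in ``log(ecc + ring_r0_deg)``.
    ring_duty_steps : ring thickness expressed in sweep steps.
    """

    cycle_s: float = 120.0
    n_cycles: int = 2
    blank_s: float = 48.0
    frame_duration_s: float = 2.0
    field_radius_deg: float = 6.5
    wedge_width_deg: float = 18.0
    direction: str = "cw_expand"
    ring_r0_deg: float = 0.35
    ring_duty_steps: int = 6

    def __post_init__(self) -> None:
        if self.direction not in ("cw_expand", "ccw_contract"):
            raise StimulusConfigError(f"unknown direction {self.direction!r}")
        for name in ("cycle_s", "blank_s"):
            dur = getattr(self, name)
            if abs(dur / self.frame_duration_s - round(dur / self.frame_duration_s)) > 1e-9:
                raise StimulusConfigError(
                    f"{name}={dur} not divisible by frame_duration_s={self.frame_duration_s}"
                )

    @property
    def cycle_frames(self) -> int:
        return int(round(self.cycle_s / self.frame_duration_s))

    @property
    def blank_frames(self) -> int:
        return int(round(self.blank_s / self.frame_duration_s))

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.cycle_frames + self.blank_frames

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_s + self.blank_s

    def acquired_volumes(self, n_dummy: int = 4) -> int:
        """Scanner volumes for one run, including dummy volumes."""
        return self.n_frames + n_dummy

    def reversed_direction(self) -> "StimulusDesign":
        other = "ccw_contract" if self.direction == "cw_expand" else "cw_expand"
        return replace(self, direction=other)


@dataclass
class StimulusAperture:
    """Binary aperture stack ``frames[iy, ix, t]`` with its design metadata."""

    frames: np.ndarray
    design: StimulusDesign
    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)

    @property
    def n_pix(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def field_radius_deg(self) -> float:
        return self.design.field_radius_deg

    @property
    def frame_duration_s(self) -> float:
        return self.design.frame_duration_s

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center meshgrid ``(X, Y)`` in degrees, ``[iy, ix]`` indexed."""
        return np.meshgrid(self.xs, self.ys)


def pixel_grid(n_pix: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric pixel-center coordinates spanning ``[-radius, +radius]``."""
    xs = np.linspace(-radius, radius, n_pix)
    return xs, xs.copy()


def _log_ecc(u: np.ndarray | float, radius: float, r0: float) -> np.ndarray:
    """Eccentricity whose log-spaced coordinate is ``u`` in [0, 1]."""
    lo, hi = np.log(r0), np.log(radius + r0)
    return np.exp(lo + np.asarray(u, dtype=float) * (hi - lo)) - r0


def build_wedge_ring(design: StimulusDesign, n_pix: int = 101) -> StimulusAperture:
    """Render the wedge-and-ring aperture sequence for one scan.

    The wedge starts at 3 o'clock and makes one revolution per cycle
    (clockwise for ``cw_expand``, counter-clockwise for ``ccw_contract``);
    the ring sweeps eccentricity once per cycle (outward for ``cw_expand``,
    inward for ``ccw_contract``) with borders equally spaced in
    ``log(ecc + r0)``.  Trailing frames are blank.
    """
    if n_pix < 26:
        raise StimulusConfigError(f"n_pix={n_pix} too small; need >= 26")
    radius = design.field_radius_deg
    xs, ys = pixel_grid(n_pix, radius)
    X, Y = np.meshgrid(xs, ys)
    ecc = np.hypot(X, Y)
    theta = np.arctan2(Y, X)  # radians, 0 at 3 o'clock, CCW positive
    in_field = ecc <= radius

    K = design.cycle_frames
    half_wedge = np.deg2rad(design.wedge_width_deg) / 2.0
    frames = np.zeros((n_pix, n_pix, design.n_frames), dtype=np.uint8)

    for t in range(design.n_cycles * K):
        k = t % K
        if design.direction == "cw_expand":
            wedge_center = -2.0 * np.pi * k / K
            ring_step = k
        else:
            wedge_center = +2.0 * np.pi * k / K
            ring_step = K - 1 - k
        dtheta = np.angle(np.exp(1j * (theta - wedge_center)))
        wedge = np.abs(dtheta) <= half_wedge
        r_in = _log_ecc(ring_step / K, radius, design.ring_r0_deg)
        r_out = _log_ecc(min(1.0, (ring_step + design.ring_duty_steps) / K),
                         radius, design.ring_r0_deg)
        ring = (ecc >= r_in) & (ecc < r_out)
        frames[:, :, t] = ((wedge | ring) & in_field).astype(np.uint8)

    return StimulusAperture(frames=frames, design=design, xs=xs, ys=ys)


def squeeze_vertical(aperture: StimulusAperture, scale: float) -> StimulusAperture:
    """Compress the aperture vertically by ``scale`` (horizontal unchanged).

    Emulates display setups where the projected stimulus does not cover
    the full vertical extent.  A pixel at (x, y) in the squeezed aperture
    shows what the original aperture showed at (x, y / scale).
    """
    if not 0.0 < scale <= 1.0:
        raise StimulusConfigError(f"scale must be in (0, 1], got {scale}")
    if scale == 1.0:
        return StimulusAperture(frames=aperture.frames.copy(), design=aperture.design,
                                xs=aperture.xs.copy(), ys=aperture.ys.copy())
    ys = aperture.ys
    src_y = ys / scale
    # nearest-neighbour resample along the vertical axis; outside rows blank
    idx = np.searchsorted(ys, src_y)
    idx = np.clip(idx, 1, len(ys) - 1)
    left = ys[idx - 1]
    right = ys[idx]
    nearest = np.where(np.abs(src_y - left) <= np.abs(right - src_y), idx - 1, idx)
    valid = np.abs(src_y) <= ys[-1] + 1e-12
    frames = np.zeros_like(aperture.frames)
    frames[valid, :, :] = aperture.frames[nearest[valid], :, :]
    return StimulusAperture(frames=frames, design=aperture.design,
                            xs=aperture.xs.copy(), ys=aperture.ys.copy())


def time_average_map(aperture: StimulusAperture, window_frames: int = 12) -> np.ndarray:
    """Per-pixel mean of moving-window means over the full presentation.

    A 12-TR (24 s) window is comparable to the duration of a typical
    haemodynamic response; the resulting map exposes how unevenly the
    wedge-and-ring configuration stimulates the field over time.
    """
    n = aperture.n_frames
    if window_frames > n:
        raise StimulusConfigError(
            f"window_frames={window_frames} exceeds n_frames={n}")
    cum = np.cumsum(aperture.frames.astype(float), axis=2)
    cum = np.concatenate([np.zeros(aperture.frames.shape[:2] + (1,)), cum], axis=2)
    win = (cum[:, :, window_frames:] - cum[:, :, :-window_frames]) / window_frames
    return win.mean(axis=2)
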