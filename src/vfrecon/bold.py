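"""Shared BOLD forward model: Gaussian receptive fields, canonical HRF,
predicted time series, variance explained and cycle averaging.

Both estimators (conventional pRF fitting and micro-probing) predict a
voxel's response as the overlap between a 2D Gaussian receptive field
and the binary stimulus aperture, convolved with a canonical
double-gamma haemodynamic response function sampled at the TR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimulus import StimulusAperture, StimulusDesign

__all__ = [
    "GaussianRF",
    "HRFSpec",
    "VoxelTimeSeries",
    "rf_field",
    "canonical_hrf",
    "predict_bold",
    "variance_explained",
    "average_cycles",
]


@dataclass(frozen=True)
class GaussianRF:
    """Isotropic 2D Gaussian receptive field (un-normalised, peak 1)."""

    x0: float
    y0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM-style defaults).

    Response and undershoot gammas have shape ``delay / dispersion`` and
    scale ``dispersion``; the undershoot is divided by ``ratio``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    ratio: float = 6.0
    duration_s: float = 32.0
    tr_s: float = 2.0


@dataclass
class VoxelTimeSeries:
    """One voxel's BOLD series plus its anatomical labels."""

    values: np.ndarray
    voxel_id: int
    hemisphere: str = "left"
    area: str = "V1"
    roi_group: str = "early"
    sub_roi: int = 1


def rf_field(rf: GaussianRF, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Evaluate the RF on a pixel grid; ``out[iy, ix]``, value 1 at the center."""
    X, Y = np.meshgrid(np.asarray(xs, float), np.asarray(ys, float))
    return np.exp(-((X - rf.x0) ** 2 + (Y - rf.y0) ** 2) / (2.0 * rf.sigma**2))


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Double-gamma HRF sampled at the TR, peak-normalised to 1."""
    if spec.tr_s <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, spec.duration_s, spec.tr_s)
    peak = stats.gamma.pdf(t, a=spec.peak_delay_s / spec.peak_dispersion_s,
                           scale=spec.peak_dispersion_s)
    under = stats.gamma.pdf(t, a=spec.undershoot_delay_s / spec.undershoot_dispersion_s,
                            scale=spec.undershoot_dispersion_s)
    h = peak - under / spec.ratio
    return h / h.max()


def convolve_hrf(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution at TR resolution, truncated to the input
    length.  ``neural`` may be 1D ``(T,)`` or 2D ``(n, T)``."""
    neural = np.asarray(neural, float)
    if neural.ndim == 1:
        return np.convolve(neural, kernel)[: neural.shape[0]]
    T = neural.shape[-1]
    full = np.apply_along_axis(lambda v: np.convolve(v, kernel)[:T], -1, neural)
    return full


def predict_bold(
    rf: GaussianRF,
    aperture: StimulusAperture,
    spec: HRFSpec,
    amplitude: float = 1.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Predicted BOLD series: RF/aperture overlap convolved with the HRF.

    ``p(t) = sum_pixels rf_field * S(., ., t)``;
    ``prediction = baseline + amplitude * (p * HRF)``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    field = rf_field(rf, aperture.xs, aperture.ys)
    p = np.einsum("yx,yxt->t", field, aperture.frames.astype(float))
    kernel = canonical_hrf(spec)
    return baseline + amplitude * convolve_hrf(p, kernel)


def variance_explained(pred: np.ndarray, data: np.ndarray, clip: bool = False) -> float:
    """VE = 1 - SS_res / SS_tot (SS_tot about the data mean).

    Raw VE can be negative for a bad model; pass ``clip=True`` to clamp
    to [0, 1] for thresholding/weighting.  Constant data is undefined.
    """
    pred = np.asarray(pred, float)
    data = np.asarray(data, float)
    if pred.shape != data.shape:
        raise ValueError("pred and data must have equal length")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot < 1e-300:
        raise ValueError("variance explained undefined for constant data")
    ve = 1.0 - float(np.sum((data - pred) ** 2)) / ss_tot
    if clip:
        ve = min(1.0, max(0.0, ve))
    return ve


def average_cycles(raw: np.ndarray, design: StimulusDesign) -> np.ndarray:
    """Average the repeated stimulus cycles (and keep the blank average).

    Returns one cycle of frame-wise means over the ``n_cycles`` repeats
    followed by the blank frames, halving white-noise variance for two
    cycles.  Works on 1D ``(T,)`` or 2D ``(n, T)`` input.
    """
    raw = np.asarray(raw, float)
    T = raw.shape[-1]
    if T != design.n_frames:
        raise ValueError(f"series length {T} != design n_frames {design.n_frames}")
    K, B = design.cycle_frames, design.blank_frames
    cycles = raw[..., : design.n_cycles * K].reshape(raw.shape[:-1] + (design.n_cycles, K))
    avg = cycles.mean(axis=-2)
    blank = raw[..., design.n_cycles * K:]
    return np.concatenate([avg, blank], axis=-1)
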