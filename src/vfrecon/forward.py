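"""Pixel-level prediction bank shared by the pRF and micro-probing fits.

Because the RF/aperture overlap and the HRF convolution are both linear,
the predicted (cycle-averaged, multi-scan concatenated) time series of
*any* receptive field is a pixel-weighted combination of per-pixel
responses.  Building those once per stimulus makes grid search, nonlinear
refinement and micro-probe evaluation cheap:

* an arbitrary Gaussian's prediction is a separable ``g_y^T B g_x``
  contraction of the bank ``B``;
* a micro-probe (sigma = 0.01 deg, far below pixel pitch) reduces to
  bilinear interpolation between the four neighbouring pixel responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bold import HRFSpec, canonical_hrf, average_cycles
from .stimulus import StimulusAperture


@dataclass
class PredictionBank:
    """Convolved, cycle-averaged per-pixel responses ``bank[iy, ix, t]``."""

    bank: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    field_radius_deg: float

    @property
    def n_pix(self) -> int:
        return self.bank.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bank.shape[2]

    def flat(self) -> np.ndarray:
        """View as ``(n_pix * n_pix, T)`` with row = iy * n_pix + ix."""
        return self.bank.reshape(-1, self.bank.shape[2])

    def gaussian_prediction(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        """Prediction for a unit-amplitude Gaussian RF via separable contraction."""
        gx = np.exp(-((self.xs - x0) ** 2) / (2.0 * sigma**2))
        gy = np.exp(-((self.ys - y0) ** 2) / (2.0 * sigma**2))
        n_y, n_x, T = self.bank.shape
        A = (gy @ self.bank.reshape(n_y, n_x * T)).reshape(n_x, T)
        return gx @ A

    def probe_prediction(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear-interpolated pixel responses at probe positions.

        ``x``/``y`` are arrays of probe coordinates (deg); returns
        ``(len(x), T)``.  Matches ``predict_bold`` with a 0.01-deg probe
        to well under 1% RMS because the probe is far narrower than a
        pixel.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        xs, ys = self.xs, self.ys
        dx = xs[1] - xs[0]
        fx = np.clip((x - xs[0]) / dx, 0.0, len(xs) - 1.0 - 1e-9)
        fy = np.clip((y - ys[0]) / dx, 0.0, len(ys) - 1.0 - 1e-9)
        ix, iy = fx.astype(int), fy.astype(int)
        B = self.flat()
        # interpolate in the bank's own dtype (float32 banks stay float32)
        wx = (fx - ix).astype(B.dtype)
        wy = (fy - iy).astype(B.dtype)
        n = len(xs)
        p00 = B[iy * n + ix]
        p01 = B[iy * n + ix + 1]
        p10 = B[(iy + 1) * n + ix]
        p11 = B[(iy + 1) * n + ix + 1]
        return ((1 - wy)[:, None] * ((1 - wx)[:, None] * p00 + wx[:, None] * p01)
                + wy[:, None] * ((1 - wx)[:, None] * p10 + wx[:, None] * p11))


def build_prediction_bank(
    apertures: Sequence[StimulusAperture],
    hrf: HRFSpec,
    cycle_average: bool = True,
) -> PredictionBank:
    """Convolve every pixel's stimulation course with the HRF, cycle-average
    per scan, and concatenate the scans along time."""
    if len(apertures) == 0:
        raise ValueError("need at least one aperture")
    kernel = canonical_hrf(hrf)
    pieces = []
    for ap in apertures:
        S = ap.frames.reshape(-1, ap.n_frames).astype(float)
        T = S.shape[1]
        full = np.zeros_like(S)
        # FFT-free convolution via matrix of shifted kernels would be large;
        # direct per-lag accumulation is O(T * len(kernel)) and exact.
        for lag, h in enumerate(kernel):
            if h == 0.0:
                continue
            full[:, lag:] += h * S[:, : T - lag]
        if cycle_average:
            full = average_cycles(full, ap.design)
        pieces.append(full)
    first = apertures[0]
    bank = np.concatenate(pieces, axis=1)
    return PredictionBank(
        bank=bank.reshape(first.n_pix, first.n_pix, -1),
        xs=first.xs.copy(),
        ys=first.ys.copy(),
        field_radius_deg=first.field_radius_deg,
    )
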