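"""Conventional population receptive-field (pRF) estimation.

Each voxel's cycle-averaged BOLD series is fitted with a 2D Gaussian RF
(free parameters x0, y0, sigma) by a coarse grid search over candidate
predictions followed by nonlinear refinement, selecting the model with
the highest variance explained (VE).  Amplitude and baseline are solved
in closed form per candidate (amplitude constrained non-negative: the
model describes positive responses only).

Grid defaults: 51 x 51 positions covering +-6.5 deg and 12 log-spaced
sigmas in [0.1, 5] deg.  Ties in VE break toward smaller sigma, then
smaller eccentricity (candidates are evaluated in that order, so the
first maximum wins deterministically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .forward import PredictionBank

__all__ = ["GridSpec", "PRFModel", "build_grid", "grid_search_fit",
           "refine_fit", "fit_cohort", "exhaustive_fine_search"]

VE_MIN_DEFAULT = 0.15
ECC_MAX_DEFAULT = 6.5


@dataclass(frozen=True)
class GridSpec:
    """Coarse search grid over (x0, y0, sigma)."""

    n_positions: int = 51
    extent_deg: float = 6.5
    n_sigmas: int = 12
    sigma_min: float = 0.1
    sigma_max: float = 5.0

    def positions(self) -> np.ndarray:
        return np.linspace(-self.extent_deg, self.extent_deg, self.n_positions)

    def sigmas(self) -> np.ndarray:
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_sigmas)


@dataclass
class PRFModel:
    """Fitted Gaussian pRF for one voxel."""

    voxel_id: int
    x0: float
    y0: float
    sigma: float
    amplitude: float
    baseline: float
    ve: float                    # raw VE (can be negative)
    refined: bool = False
    converged: bool = True

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def ve_clipped(self) -> float:
        return min(1.0, max(0.0, self.ve))


class CandidateGrid:
    """Precomputed candidate predictions, shared across a cohort.

    Candidates are ordered by (sigma, eccentricity) ascending so that a
    first-maximum argmax implements the documented tie-break.
    """

    def __init__(self, bank: PredictionBank, spec: GridSpec = GridSpec()):
        pos = spec.positions()
        sig = spec.sigmas()
        if pos.size == 0 or sig.size == 0:
            raise ValueError("empty pRF search grid")
        X0, Y0 = np.meshgrid(pos, pos)          # [iy0, ix0]
        preds = []
        for s in sig:
            GX = np.exp(-((pos[:, None] - bank.xs[None, :]) ** 2) / (2 * s**2))
            GY = np.exp(-((pos[:, None] - bank.ys[None, :]) ** 2) / (2 * s**2))
            A = np.einsum("ay,yxt->axt", GY, bank.bank)     # (n_y0, n_pix, T)
            preds.append(np.einsum("bx,axt->abt", GX, A))   # (n_y0, n_x0, T)
        P = np.stack(preds).reshape(-1, bank.n_frames)
        params = np.column_stack([
            np.repeat(sig, pos.size**2),
            np.tile(X0.ravel(), sig.size),
            np.tile(Y0.ravel(), sig.size),
        ])  # columns: sigma, x0, y0
        ecc = np.hypot(params[:, 1], params[:, 2])
        order = np.lexsort((ecc, params[:, 0]))
        self.params = params[order]
        P = P[order]
        self.mean = P.mean(axis=1)
        self.P0 = P - self.mean[:, None]
        self.norm2 = np.einsum("ij,ij->i", self.P0, self.P0)
        self.spec = spec
        self.bank = bank

    def ve(self, data: np.ndarray) -> np.ndarray:
        """VE of every candidate for every voxel: shape (n_cand, n_vox).

        Closed-form non-negative-amplitude least squares: with the
        amplitude clamped at zero the model reduces to the data mean and
        VE is 0, otherwise VE = r^2 of the demeaned prediction.
        """
        data = np.atleast_2d(np.asarray(data, float))
        D0 = data - data.mean(axis=1, keepdims=True)
        n2d = np.einsum("ij,ij->i", D0, D0)
        C = self.P0 @ D0.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ve = np.clip(C, 0.0, None) ** 2 / np.outer(self.norm2, n2d)
        ve[~np.isfinite(ve)] = 0.0
        ve[self.norm2 < 1e-12, :] = 0.0
        return ve


def build_grid(bank: PredictionBank, spec: GridSpec = GridSpec()) -> CandidateGrid:
    return CandidateGrid(bank, spec)


def _solve_gain(pred: np.ndarray, data: np.ndarray) -> tuple[float, float, float]:
    """Non-negative amplitude + free baseline by least squares; returns
    (amplitude, baseline, ve)."""
    p0 = pred - pred.mean()
    d0 = data - data.mean()
    n2p = float(p0 @ p0)
    n2d = float(d0 @ d0)
    if n2p < 1e-12 or n2d < 1e-300:
        return 0.0, float(data.mean()), 0.0
    c = float(p0 @ d0)
    a = max(0.0, c / n2p)
    ve = 0.0 if c <= 0 else c * c / (n2p * n2d)
    b = float(data.mean() - a * pred.mean())
    return a, b, ve


def grid_search_fit(data: np.ndarray, grid: CandidateGrid,
                    voxel_id: int = 0) -> PRFModel:
    """Coarse fit: the grid candidate maximising VE (ties break toward
    smaller sigma, then eccentricity)."""
    ve = grid.ve(data)[:, 0]
    best = int(np.argmax(ve))
    sigma, x0, y0 = grid.params[best]
    d = np.asarray(data, float).ravel()
    pred = grid.P0[best] + grid.mean[best]
    a, b, _ = _solve_gain(pred, d)
    return PRFModel(voxel_id=voxel_id, x0=float(x0), y0=float(y0),
                    sigma=float(sigma), amplitude=a, baseline=b,
                    ve=float(ve[best]))


def _ve_at(bank: PredictionBank, data: np.ndarray,
           x0: float, y0: float, sigma: float) -> float:
    pred = bank.gaussian_prediction(x0, y0, sigma)
    return _solve_gain(pred, data)[2]


def refine_fit(data: np.ndarray, coarse: PRFModel, bank: PredictionBank,
               max_ecc: float = 1.2 * ECC_MAX_DEFAULT,
               maxiter: int = 200, xatol: float = 1e-3) -> PRFModel:
    """Nelder-Mead refinement of (x0, y0, sigma) from the coarse optimum.

    The refined model is only accepted if its VE does not fall below the
    coarse VE; on optimizer failure the coarse model is returned with
    ``converged=False``.
    """
    data = np.asarray(data, float).ravel()

    def neg_ve(p):
        x0, y0, sigma = p
        if sigma <= 0.02 or np.hypot(x0, y0) > max_ecc:
            return 1.0
        return -_ve_at(bank, data, x0, y0, sigma)

    start = np.array([coarse.x0, coarse.y0, coarse.sigma])
    try:
        res = optimize.minimize(
            neg_ve, start, method="Nelder-Mead",
            options=dict(xatol=xatol, fatol=1e-10, maxiter=maxiter,
                         initial_simplex=start + np.vstack(
                             [np.zeros(3), np.diag([0.15, 0.15,
                                                    0.2 * coarse.sigma + 0.02])])))
    except Exception:
        return PRFModel(**{**coarse.__dict__, "converged": False})
    x0, y0, sigma = res.x
    ve = -neg_ve(res.x)
    if ve < coarse.ve - 1e-9:
        out = PRFModel(**coarse.__dict__)
        out.refined = True
        return out
    pred = bank.gaussian_prediction(x0, y0, sigma)
    a, b, _ = _solve_gain(pred, data)
    return PRFModel(voxel_id=coarse.voxel_id, x0=float(x0), y0=float(y0),
                    sigma=float(sigma), amplitude=a, baseline=b, ve=float(ve),
                    refined=True, converged=bool(res.success or ve >= coarse.ve))


def fit_cohort(
    data: np.ndarray,
    labels: pd.DataFrame,
    bank: PredictionBank,
    grid: CandidateGrid | None = None,
    refine: bool = True,
    ve_min: float = VE_MIN_DEFAULT,
    ecc_max: float = ECC_MAX_DEFAULT,
    refine_maxiter: int = 100,
    refine_min_ve: float = 0.10,
    chunk: int = 256,
) -> pd.DataFrame:
    """Fit every voxel and apply the inclusion gate (VE > 15%, ecc <= 6.5).

    Nonlinear refinement polishes the coarse optimum locally (VE gains of
    a few percent at most), so voxels whose coarse VE falls below
    ``refine_min_ve`` — well under the inclusion threshold — keep their
    coarse fit.

    Returns a table with the fitted parameters, raw VE, the ``included``
    mask and the carried-through labels; the per-ROI-group exclusion
    fractions are attached as ``df.attrs['exclusion_fractions']``.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n_vox = data.shape[0]
    if n_vox == 0:
        out = pd.DataFrame(columns=["voxel_id", "x0", "y0", "sigma", "amplitude",
                                    "baseline", "ve", "included"])
        out.attrs["exclusion_fractions"] = {}
        return out
    if grid is None:
        grid = build_grid(bank)
    rows = []
    for lo in range(0, n_vox, chunk):
        block = data[lo:lo + chunk]
        ve = grid.ve(block)
        best = np.argmax(ve, axis=0)
        for j, b in enumerate(best):
            i = lo + j
            sigma, x0, y0 = grid.params[b]
            pred = grid.P0[b] + grid.mean[b]
            a, base, _ = _solve_gain(pred, block[j])
            model = PRFModel(voxel_id=int(labels.iloc[i]["voxel_id"]),
                             x0=float(x0), y0=float(y0), sigma=float(sigma),
                             amplitude=a, baseline=base, ve=float(ve[b, j]))
            if refine and model.ve >= refine_min_ve:
                model = refine_fit(block[j], model, bank, maxiter=refine_maxiter)
            rows.append(model)
    out = labels.reset_index(drop=True).copy()
    for col in ("x0", "y0", "sigma", "amplitude", "baseline", "ve"):
        out[col] = [getattr(m, col) for m in rows]
    out["ecc"] = np.hypot(out["x0"], out["y0"])
    out["included"] = (out["ve"] > ve_min) & (out["ecc"] <= ecc_max)
    excl = {}
    if "roi_group" in out.columns:
        for g, sub in out.groupby("roi_group"):
            excl[g] = float(1.0 - sub["included"].mean())
    out.attrs["exclusion_fractions"] = excl
    return out


def exhaustive_fine_search(
    data: np.ndarray,
    bank: PredictionBank,
    center: tuple[float, float, float],
    span_xy: float = 0.3,
    span_sigma_factor: float = 1.45,
    pitch: float = 0.01,
) -> tuple[float, float, float, float]:
    """Independent brute-force oracle: exhaustive VE evaluation on a fine
    grid (default 0.01-deg pitch) bracketing ``center = (x0, y0, sigma)``.

    A first pass at 5x the pitch locates the basin, a second pass at the
    requested pitch resolves it.  Returns (x0, y0, sigma, ve).
    """
    data = np.asarray(data, float).ravel()
    x0c, y0c, sc = center

    def scan(xv, yv, sv):
        best = (x0c, y0c, sc, -np.inf)
        for s in sv:
            GY = np.exp(-((yv[:, None] - bank.ys[None, :]) ** 2) / (2 * s**2))
            GX = np.exp(-((xv[:, None] - bank.xs[None, :]) ** 2) / (2 * s**2))
            A = np.einsum("ay,yxt->axt", GY, bank.bank)
            P = np.einsum("bx,axt->abt", GX, A).reshape(-1, bank.n_frames)
            P0 = P - P.mean(axis=1, keepdims=True)
            n2p = np.einsum("ij,ij->i", P0, P0)
            d0 = data - data.mean()
            n2d = float(d0 @ d0)
            c = P0 @ d0
            with np.errstate(divide="ignore", invalid="ignore"):
                ve = np.clip(c, 0.0, None) ** 2 / (n2p * n2d)
            ve[~np.isfinite(ve)] = 0.0
            k = int(np.argmax(ve))
            if ve[k] > best[3]:
                iy, ix = divmod(k, xv.size)
                best = (float(xv[ix]), float(yv[iy]), float(s), float(ve[k]))
        return best

    coarse_pitch = 5 * pitch
    xv = np.arange(x0c - span_xy, x0c + span_xy + 1e-9, coarse_pitch)
    yv = np.arange(y0c - span_xy, y0c + span_xy + 1e-9, coarse_pitch)
    sv = np.arange(sc / span_sigma_factor, sc * span_sigma_factor, coarse_pitch)
    x1, y1, s1, _ = scan(xv, yv, sv)
    xv = np.arange(x1 - 6 * pitch, x1 + 6 * pitch + 1e-9, pitch)
    yv = np.arange(y1 - 6 * pitch, y1 + 6 * pitch + 1e-9, pitch)
    sv = np.arange(max(0.02, s1 - 6 * pitch), s1 + 6 * pitch + 1e-9, pitch)
    return scan(xv, yv, sv)
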