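"""Downstream comparisons: sensitivity distributions, pRF-vs-MP quantile
and regression analyses, voxel-contribution statistics, and concordance
with perimetry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PerimetryGrid
from .reconstruction import TotalDeviationMap, ci_boundaries, CI_LEVELS

__all__ = ["SensitivityDistribution", "pool_sensitivities", "qq_points",
           "linear_vs_polynomial", "contribution_table", "contribution_stats",
           "perimetry_concordance"]


@dataclass
class SensitivityDistribution:
    """Pooled dB sensitivities for one group/technique with CI bounds."""

    group: str
    technique: str
    values: np.ndarray
    boundaries: dict[int, tuple[float, float]] = field(default_factory=dict)


def _hemifield_mask(td: TotalDeviationMap, hemisphere: str) -> np.ndarray:
    """Cells represented by ``hemisphere``: contralateral attribution
    (x < 0 belongs to the right hemisphere and vice versa); cells on the
    vertical meridian belong to both.  With an even bin count no cell
    center sits exactly on the meridian."""
    n = td.db.shape[1]
    width = 2.0 * td.extent / n
    xc = -td.extent + width * (np.arange(n) + 0.5)
    if hemisphere == "right":
        col = xc <= 0
    elif hemisphere == "left":
        col = xc >= 0
    else:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return np.broadcast_to(col[None, :], td.db.shape)


def pool_sensitivities(td_maps: list[TotalDeviationMap], group: str,
                       technique: str,
                       hemisphere: str | None = None,
                       levels=CI_LEVELS) -> SensitivityDistribution:
    """Pool valid dB cells over maps (optionally one hemisphere's
    representation only) and attach CI boundaries at all levels."""
    pools = []
    for td in td_maps:
        mask = td.valid.copy()
        if hemisphere is not None:
            mask &= _hemifield_mask(td, hemisphere)
        pools.append(td.db[mask])
    values = np.concatenate(pools) if pools else np.array([])
    if values.size == 0:
        raise ValueError(f"no values pooled for group {group!r}")
    return SensitivityDistribution(group=group, technique=technique,
                                   values=values,
                                   boundaries=ci_boundaries(values, levels))


def qq_points(a: np.ndarray, b: np.ndarray, n_quantiles: int = 99) -> np.ndarray:
    """Matched quantiles of two samples at equally spaced probabilities.

    Returns ``(n_quantiles, 2)``; when the distributions agree the points
    fall on the identity line.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    p = np.linspace(0.0, 1.0, n_quantiles + 2)[1:-1]
    return np.column_stack([np.quantile(a, p), np.quantile(b, p)])


def _steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate two predictors with the same outcome on
    the same sample of size ``n``; ``r12`` is the predictors' mutual
    correlation.  Returns (z, two-sided p).
    """
    r1 = np.clip(r1, -0.999999, 0.999999)
    r2 = np.clip(r2, -0.999999, 0.999999)
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = ((r1 + r2) / 2.0) ** 2
    # Steiger (1980) covariance of the Fisher transforms
    num = r12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12**2)
    cov = num / (1.0 - rbar2) ** 2
    denom = 2.0 * (1.0 - cov) / max(n - 3, 1)
    if denom <= 0:
        return 0.0, 1.0
    z = abs(z1 - z2) / np.sqrt(denom)
    p = 2.0 * stats.norm.sf(z)
    return float(z), float(p)


def linear_vs_polynomial(x: np.ndarray, y: np.ndarray, degree: int = 2) -> dict:
    """Compare a linear and a degree-``degree`` polynomial least-squares fit.

    ``R`` for each model is the Pearson correlation between fitted and
    observed y.  Because the two sets of fitted values come from the same
    sample, the correlations are compared with Steiger's dependent-
    correlation z (two-sided p).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points, got {n}")
    lin = np.polyval(np.polyfit(x, y, 1), x)
    poly = np.polyval(np.polyfit(x, y, degree), x)
    r_lin = float(np.corrcoef(lin, y)[0, 1])
    r_poly = float(np.corrcoef(poly, y)[0, 1])
    r12 = float(np.corrcoef(lin, poly)[0, 1])
    z, p = _steiger_z(r_poly, r_lin, r12, n)
    return dict(R_lin=r_lin, R_poly=r_poly, z=z, p=p, degree=degree, n=n)


def contribution_table(fits: dict[object, pd.DataFrame],
                       lesioned_hemisphere: dict[object, str] | None = None
                       ) -> pd.DataFrame:
    """Per-participant counts/proportions of included voxels by hemisphere
    x ROI group.

    ``fits`` maps participant id -> voxel table with ``included``,
    ``hemisphere`` and ``roi_group`` columns.  If
    ``lesioned_hemisphere`` is given, hemispheres are relabelled
    lesioned/healthy; controls keep left/right.
    """
    rows = []
    for pid, df in fits.items():
        inc = df[df["included"]]
        total = max(len(inc), 1)
        lh = (lesioned_hemisphere or {}).get(pid)
        for hemi in ("left", "right"):
            for grp in ("early", "extrastriate"):
                count = int(((inc["hemisphere"] == hemi)
                             & (inc["roi_group"] == grp)).sum())
                side = hemi if lh is None else ("lesioned" if hemi == lh else "healthy")
                rows.append(dict(participant=pid, hemisphere=side, roi_group=grp,
                                 count=count, proportion=count / total))
    return pd.DataFrame(rows)


def contribution_stats(table: pd.DataFrame,
                       blindsight: dict[object, bool] | None = None) -> dict:
    """Paired tests on informative-voxel proportions.

    * lesioned vs healthy hemisphere (overall and within early /
      extrastriate): paired t-tests;
    * early vs extrastriate within each hemisphere: paired t-tests;
    * blindsight-positive vs -negative lesioned-hemisphere proportions:
      Mann-Whitney U (two-sided).

    All proportions are per participant and sum to 1 by construction
    (asserted).
    """
    piv = table.pivot_table(index="participant", columns=["hemisphere", "roi_group"],
                            values="proportion", aggfunc="sum", fill_value=0.0)
    totals = piv.sum(axis=1).to_numpy()
    if not np.allclose(totals[totals > 0], 1.0, atol=1e-9):
        raise AssertionError("per-participant proportions must sum to 1")
    hemis = sorted({h for h, _ in piv.columns})
    if set(hemis) != {"lesioned", "healthy"}:
        raise ValueError("contribution_stats expects lesioned/healthy labels")

    def prop(hemi, grp=None):
        if grp is None:
            cols = [c for c in piv.columns if c[0] == hemi]
        else:
            cols = [c for c in piv.columns if c == (hemi, grp)]
        return piv[cols].sum(axis=1).to_numpy()

    out = {"n_participants": int(len(piv))}

    def paired(a, b, name):
        if np.allclose(a, b):
            out[name] = dict(t=0.0, df=len(a) - 1, p=1.0)
        else:
            t = stats.ttest_rel(a, b)
            out[name] = dict(t=float(t.statistic), df=int(len(a) - 1),
                             p=float(t.pvalue))

    paired(prop("healthy"), prop("lesioned"), "healthy_vs_lesioned")
    for grp in ("early", "extrastriate"):
        paired(prop("healthy", grp), prop("lesioned", grp),
               f"healthy_vs_lesioned_{grp}")
    for hemi in ("lesioned", "healthy"):
        paired(prop(hemi, "early"), prop(hemi, "extrastriate"),
               f"early_vs_extrastriate_{hemi}")
    if blindsight:
        lesioned = prop("lesioned")
        pos = np.array([lesioned[i] for i, pid in enumerate(piv.index)
                        if blindsight.get(pid)])
        neg = np.array([lesioned[i] for i, pid in enumerate(piv.index)
                        if blindsight.get(pid) is False])
        if pos.size and neg.size:
            u = stats.mannwhitneyu(neg, pos, alternative="two-sided",
                                   method="exact" if min(pos.size, neg.size) < 8
                                   else "auto")
            out["blindsight_mannwhitney"] = dict(U=float(u.statistic),
                                                 p=float(u.pvalue),
                                                 n_pos=int(pos.size),
                                                 n_neg=int(neg.size))
    return out


def perimetry_concordance(td: TotalDeviationMap, grid: PerimetryGrid,
                          overlap_radius: float = 3.0,
                          k_nearest: int = 4,
                          blind_threshold_db: float = 5.0) -> dict:
    """Concordance between the fMRI classification and perimetry.

    Each in-field perimetry point is summarised by the modal label of the
    ``k_nearest`` valid TD cells within ``overlap_radius`` (ties resolve
    to "within"); a perimetry location measures a small patch of field,
    so the nearest map cells — not the whole overlap disc — carry its
    fMRI counterpart.  Reports the fraction of perimetrically blind
    points labelled below normal, the fraction of sighted points labelled
    within-or-above, and the blind points whose fMRI label is
    within-or-above ("retained sensitivity" candidates).
    """
    if td.labels is None:
        raise ValueError("total-deviation map must be classified first")
    in_field = grid.in_field(td.extent)
    if not in_field.any():
        raise ValueError("no perimetry points inside the reconstructed field")
    n = td.db.shape[0]
    width = 2.0 * td.extent / n
    c = -td.extent + width * (np.arange(n) + 0.5)
    X, Y = np.meshgrid(c, c)
    blind = grid.blind_mask(blind_threshold_db)

    summaries = []
    for (px, py), is_blind in zip(grid.locations[in_field], blind[in_field]):
        dist = np.hypot(X - px, Y - py)
        near = (dist <= overlap_radius) & td.valid
        cell_labels = td.labels[near]
        if cell_labels.size == 0:
            summaries.append((is_blind, "masked"))
            continue
        if cell_labels.size > k_nearest:
            order = np.argsort(dist[near])[:k_nearest]
            cell_labels = cell_labels[order]
        counts = {lab: int((cell_labels == lab).sum())
                  for lab in ("below", "within", "above")}
        top = max(counts.values())
        winners = [lab for lab, cnt in counts.items() if cnt == top]
        label = winners[0] if len(winners) == 1 else "within"
        summaries.append((bool(is_blind), label))

    blind_pts = [lab for is_blind, lab in summaries if is_blind and lab != "masked"]
    sighted_pts = [lab for is_blind, lab in summaries if not is_blind and lab != "masked"]
    report = dict(
        n_in_field=int(in_field.sum()),
        n_blind=len(blind_pts),
        n_sighted=len(sighted_pts),
        blind_below_fraction=(np.mean([lab == "below" for lab in blind_pts])
                              if blind_pts else np.nan),
        sighted_within_or_above_fraction=(np.mean([lab in ("within", "above")
                                                   for lab in sighted_pts])
                                          if sighted_pts else np.nan),
        retained_sensitivity_count=int(sum(lab in ("within", "above")
                                           for lab in blind_pts)),
    )
    return report
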