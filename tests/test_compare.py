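"""Distribution pooling, Q-Q, linear-vs-polynomial, contribution statistics,
perimetry concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vfrecon import (linear_vs_polynomial, perimetry_concordance,
                     pool_sensitivities, qq_points)
from vfrecon.cohort import PerimetryGrid
from vfrecon.compare import contribution_stats, contribution_table
from vfrecon.reconstruction import TotalDeviationMap, classify_deviation


def _td(db, valid=None):
    db = np.asarray(db, float)
    return TotalDeviationMap(db=db,
                             valid=np.ones_like(db, bool) if valid is None else valid)


class TestPooling:
    def test_all_zero_map_gives_zero_boundaries(self):
        dist = pool_sensitivities([_td(np.zeros((26, 26)))], "controls", "mp")
        assert all(lo == hi == 0.0 for lo, hi in dist.boundaries.values())

    def test_order_statistics_verified_by_sorting(self):
        vals = np.arange(20, dtype=float)
        td = _td(vals.reshape(4, 5))
        dist = pool_sensitivities([td], "controls", "prf")
        lo, hi = dist.boundaries[90]
        assert lo == pytest.approx(np.percentile(vals, 5))
        assert hi == pytest.approx(np.percentile(vals, 95))

    def test_hemisphere_attribution_is_contralateral(self):
        db = np.zeros((26, 26))
        db[:, :13] = -5.0      # left half of the field (x < 0)
        td = _td(db)
        right = pool_sensitivities([td], "patients", "mp", hemisphere="right")
        left = pool_sensitivities([td], "patients", "mp", hemisphere="left")
        assert (right.values == -5.0).all()     # right hemisphere sees x < 0
        assert (left.values == 0.0).all()


class TestQQ:
    def test_identical_samples_on_identity(self):
        a = np.random.default_rng(0).normal(size=300)
        pts = qq_points(a, a, 19)
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_shift_moves_points_off_identity_by_constant(self):
        a = np.random.default_rng(1).normal(size=500)
        pts = qq_points(a, a + 2.0, 19)
        assert np.allclose(pts[:, 1] - pts[:, 0], 2.0)

    def test_floored_sample_plateaus(self):
        # censoring one sample at -1 creates a flat run of quantiles — the
        # signature of the MP floor in the patient comparison
        rng = np.random.default_rng(2)
        a = rng.normal(size=5000)
        b = np.maximum(a, -1.0)
        pts = qq_points(a, b, 99)
        low = pts[pts[:, 0] < -1.1]
        assert low.size > 0
        assert np.ptp(low[:, 1]) < 0.05     # b-quantiles flat below the floor

    def test_invariance_to_ordering_and_duplication(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=100), rng.normal(size=80)
        base = qq_points(a, b, 9)
        assert np.allclose(base, qq_points(np.sort(a), b[::-1], 9))
        assert np.allclose(base, qq_points(np.tile(a, 2), np.tile(b, 2), 9))


class TestLinearVsPolynomial:
    def test_exactly_linear_data(self):
        x = np.linspace(-1, 1, 50)
        y = 3 * x + 1
        out = linear_vs_polynomial(x, y)
        assert out["R_lin"] == pytest.approx(1.0)
        assert out["R_poly"] == pytest.approx(1.0)
        assert out["z"] == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_prefers_polynomial(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, 400)
        y = x**2 + rng.normal(0, 0.05, 400)
        out = linear_vs_polynomial(x, y)
        assert out["R_poly"] > out["R_lin"]
        assert out["z"] > 2.0
        assert out["p"] < 0.05

    def test_degree_one_comparison_is_null(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=60), rng.normal(size=60)
        out = linear_vs_polynomial(x, y, degree=1)
        assert out["R_lin"] == pytest.approx(out["R_poly"], abs=1e-12)
        assert out["z"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_vs_polynomial([0, 1, 2], [1, 2, 3], degree=2)


def _fits(per_participant):
    """participant -> (hemi, grp, n_included) triples -> label DataFrame."""
    out = {}
    for pid, triples in per_participant.items():
        rows = []
        vid = 0
        for hemi, grp, n in triples:
            for _ in range(n):
                rows.append(dict(voxel_id=vid, hemisphere=hemi,
                                 roi_group=grp, included=True))
                vid += 1
        out[pid] = pd.DataFrame(rows)
    return out


class TestContributions:
    def test_proportions_sum_to_one(self):
        fits = _fits({"P1": [("left", "early", 3), ("right", "extrastriate", 7)]})
        table = contribution_table(fits, {"P1": "left"})
        assert table.groupby("participant")["proportion"].sum().iloc[0] == 1.0

    def test_identical_hemispheres_give_t_zero(self):
        fits = _fits({f"P{i}": [("left", "early", 5), ("right", "early", 5)]
                      for i in range(4)})
        table = contribution_table(fits, {f"P{i}": "left" for i in range(4)})
        out = contribution_stats(table)
        assert out["healthy_vs_lesioned"]["t"] == 0.0

    def test_hand_computed_paired_t(self):
        # three patients; healthy-minus-lesioned proportion differences are
        # d = (0.2, 0.4, 0.6): t = mean/ (sd/sqrt(3)) = 0.4/(0.2/sqrt(3))
        spec = {"P1": [("left", "early", 4), ("right", "early", 6)],
                "P2": [("left", "early", 3), ("right", "early", 7)],
                "P3": [("left", "early", 2), ("right", "early", 8)]}
        table = contribution_table(_fits(spec), {p: "left" for p in spec})
        out = contribution_stats(table)
        expect = 0.4 / (0.2 / np.sqrt(3))
        assert out["healthy_vs_lesioned"]["t"] == pytest.approx(expect)
        assert out["healthy_vs_lesioned"]["df"] == 2

    def test_complete_separation_gives_u_zero(self):
        spec = {}
        blind = {}
        for i, n_lesioned in enumerate([1, 1, 2]):       # negatives: low
            spec[f"N{i}"] = [("left", "early", n_lesioned),
                             ("right", "early", 10 - n_lesioned)]
            blind[f"N{i}"] = False
        for i, n_lesioned in enumerate([4, 5, 5, 6]):    # positives: high
            spec[f"B{i}"] = [("left", "early", n_lesioned),
                             ("right", "early", 10 - n_lesioned)]
            blind[f"B{i}"] = True
        table = contribution_table(_fits(spec), {p: "left" for p in spec})
        out = contribution_stats(table, blindsight=blind)
        assert out["blindsight_mannwhitney"]["U"] == 0.0


class TestPerimetryConcordance:
    def _grid(self, values):
        locs = np.array([[3.0, 3.0], [3.0, -3.0], [-3.0, 3.0], [-3.0, -3.0]])
        return PerimetryGrid(locations=locs, values=np.asarray(values, float),
                             grid_type="24-2", mode="db")

    def test_perfect_agreement(self):
        db = np.zeros((26, 26))
        db[:, 13:] = -30.0                    # right hemifield dead
        td = classify_deviation(_td(db), {90: (-2.0, 2.0)})
        grid = self._grid([0.0, 0.0, 30.0, 30.0])   # x>0 blind, x<0 sighted
        rep = perimetry_concordance(td, grid)
        assert rep["blind_below_fraction"] == 1.0
        assert rep["sighted_within_or_above_fraction"] == 1.0
        assert rep["retained_sensitivity_count"] == 0

    def test_blind_perimetry_but_normal_fmri_counts_retained(self):
        td = classify_deviation(_td(np.zeros((26, 26))), {90: (-2.0, 2.0)})
        grid = self._grid([0.0, 0.0, 0.0, 0.0])
        rep = perimetry_concordance(td, grid)
        assert rep["retained_sensitivity_count"] == rep["n_blind"] == 4

    def test_out_of_field_points_ignored(self):
        td = classify_deviation(_td(np.zeros((26, 26))), {90: (-2.0, 2.0)})
        locs = np.array([[3.0, 3.0], [21.0, 3.0]])
        grid = PerimetryGrid(locations=locs, values=np.array([30.0, 0.0]),
                             grid_type="24-2", mode="db")
        rep = perimetry_concordance(td, grid)
        assert rep["n_in_field"] == 1

    def test_unclassified_map_rejected(self):
        with pytest.raises(ValueError):
            perimetry_concordance(_td(np.zeros((26, 26))), self._grid([0, 0, 0, 0]))


class TestPlots:
    def test_figures_written(self, tmp_path):
        from vfrecon.plots import (plot_qq, plot_scatter_fits,
                                   plot_sensitivity_distributions)
        rng = np.random.default_rng(0)
        dist = pool_sensitivities([_td(rng.normal(size=(26, 26)))],
                                  "controls", "mp")
        p1 = plot_sensitivity_distributions([dist], tmp_path / "dist.png")
        pts = qq_points(rng.normal(size=200), rng.normal(size=200), 19)
        p2 = plot_qq(pts, tmp_path / "qq.png")
        x = rng.uniform(-1, 1, 100)
        y = x**2 + rng.normal(0, 0.1, 100)
        res = linear_vs_polynomial(x, y)
        p3 = plot_scatter_fits(x, y, res, tmp_path / "scatter.png")
        assert all(p.stat().st_size > 0 for p in (p1, p2, p3))
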