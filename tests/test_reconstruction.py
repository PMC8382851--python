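"""Coverage maps, normative referencing, dB conversion, CI classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vfrecon import (CoverageMap, EmptyROIError, bin_probe_map,
                     build_normative_map, ci_boundaries, classify_deviation,
                     combine_and_normalize, coverage_from_prfs,
                     coverage_from_probes, total_deviation_db)
from vfrecon.microprobe import ProbeMap
from vfrecon.reconstruction import NormativeMap, cell_centers


def _prf_df(rows):
    df = pd.DataFrame(rows, columns=["voxel_id", "x0", "y0", "sigma", "ve"])
    df["included"] = df["ve"] > 0.15
    return df


def _cm(grid, technique="mp", normalized=False):
    return CoverageMap(grid=np.asarray(grid, float), technique=technique,
                       normalized=normalized)


def _probe_map(vid, x, y, ve):
    probes = np.array([[x, y, ve]])
    vsum, vmax, _ = bin_probe_map(probes)
    return ProbeMap(voxel_id=vid, probes=probes, binned=vsum, binned_max=vmax)


class TestCoverageFromPRFs:
    def test_single_voxel_is_scaled_gaussian(self):
        cm = coverage_from_prfs(_prf_df([[0, 1.0, -1.0, 0.8, 0.5]]))
        c = cell_centers()
        X, Y = np.meshgrid(c, c)
        expect = 0.5 * np.exp(-((X - 1.0) ** 2 + (Y + 1.0) ** 2) / (2 * 0.8**2))
        assert np.allclose(cm.grid, expect)

    def test_two_identical_voxels_double(self):
        one = coverage_from_prfs(_prf_df([[0, 1.0, 1.0, 0.7, 0.4]]))
        two = coverage_from_prfs(_prf_df([[0, 1.0, 1.0, 0.7, 0.4],
                                          [1, 1.0, 1.0, 0.7, 0.4]]))
        assert np.allclose(two.grid, 2 * one.grid)

    def test_only_surviving_voxels_contribute(self):
        rng = np.random.default_rng(4)
        rows = [[i, *rng.uniform(-3, 3, 2), 0.7, 0.5] for i in range(14)]
        rows += [[14 + i, *rng.uniform(-3, 3, 2), 0.7, 0.05] for i in range(6)]
        full = coverage_from_prfs(_prf_df(rows))
        kept = coverage_from_prfs(_prf_df(rows[:14]))
        assert np.allclose(full.grid, kept.grid)

    def test_empty_roi_raises_unless_allowed(self):
        with pytest.raises(EmptyROIError):
            coverage_from_prfs(_prf_df([[0, 1.0, 1.0, 0.7, 0.01]]))
        cm = coverage_from_prfs(_prf_df([[0, 1.0, 1.0, 0.7, 0.01]]),
                                allow_empty=True)
        assert cm.empty and cm.grid.sum() == 0


class TestCoverageFromProbes:
    def test_single_map_identity(self):
        pm = _probe_map(0, 1.0, 1.0, 0.4)
        cm = coverage_from_probes([pm])
        assert np.allclose(cm.grid, pm.binned)

    def test_order_invariance(self):
        maps = [_probe_map(i, x, y, v) for i, (x, y, v) in
                enumerate([(1, 1, 0.3), (-2, 0.5, 0.5), (0.2, -3, 0.2)])]
        a = coverage_from_probes(maps)
        b = coverage_from_probes(maps[::-1])
        assert np.allclose(a.grid, b.grid)

    def test_mass_conservation(self):
        maps = [_probe_map(i, 0.5 * i - 2, 1.0, 0.1 * (i + 1)) for i in range(5)]
        cm = coverage_from_probes(maps)
        assert cm.grid.sum() == pytest.approx(sum(m.binned.sum() for m in maps))


class TestCombineNormalize:
    def test_identical_parts_give_normalized_part(self):
        g = np.random.default_rng(0).uniform(size=(26, 26))
        out = combine_and_normalize([_cm(g), _cm(g)])
        assert np.allclose(out.grid, g / g.max())
        assert out.grid.max() == pytest.approx(1.0)

    def test_one_empty_hemisphere_halves_then_renormalizes(self):
        g = np.random.default_rng(1).uniform(size=(26, 26))
        out = combine_and_normalize([_cm(g), _cm(np.zeros((26, 26)))])
        assert np.allclose(out.grid, g / g.max())

    def test_all_zero_mean_rejected(self):
        with pytest.raises(EmptyROIError):
            combine_and_normalize([_cm(np.zeros((26, 26)))])

    def test_mismatched_parts_rejected(self):
        with pytest.raises(ValueError):
            combine_and_normalize([_cm(np.ones((26, 26))),
                                   _cm(np.ones((13, 13)))])


class TestNormativeMap:
    def _controls(self, n=3, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n):
            g = rng.uniform(0.1, 1.0, size=(26, 26))
            out[f"C{i}"] = _cm(g / g.max(), normalized=True)
        return out

    def test_identical_controls_reproduced(self):
        g = np.random.default_rng(2).uniform(0.1, 1, (26, 26))
        cms = {k: _cm(g / g.max(), normalized=True) for k in "abc"}
        norm = build_normative_map(cms)
        assert np.allclose(norm.grid, g / g.max())

    def test_leave_one_out_excludes(self):
        cms = self._controls()
        norm = build_normative_map(cms, exclude_id="C1")
        assert "C1" not in norm.provenance
        expect = np.mean([cms["C0"].grid, cms["C2"].grid], axis=0)
        assert np.allclose(norm.grid, expect)

    def test_mean_verified_cellwise(self):
        cms = self._controls(3, seed=5)
        norm = build_normative_map(cms)
        expect = (cms["C0"].grid + cms["C1"].grid + cms["C2"].grid) / 3
        assert np.allclose(norm.grid, expect)

    def test_single_control_loo_rejected(self):
        cms = self._controls(1)
        with pytest.raises(ValueError):
            build_normative_map(cms, exclude_id="C0")

    def test_unnormalized_control_rejected(self):
        with pytest.raises(ValueError):
            build_normative_map({"a": _cm(np.ones((26, 26)) * 2)})


class TestTotalDeviation:
    def _norm(self, grid):
        return NormativeMap(grid=np.asarray(grid, float), provenance=["x"])

    def test_equal_maps_zero_db(self):
        g = np.random.default_rng(3).uniform(0.2, 1.0, (26, 26))
        td = total_deviation_db(_cm(g, normalized=True), self._norm(g))
        assert np.allclose(td.db[td.valid], 0.0)

    def test_ratio_tenth_is_minus_ten_db(self):
        g = np.ones((26, 26))
        td = total_deviation_db(_cm(0.1 * g, normalized=True), self._norm(g))
        assert np.allclose(td.db, -10.0)

    def test_zero_coverage_floors_at_minus_thirty(self):
        g = np.ones((26, 26))
        td = total_deviation_db(_cm(0.0 * g, normalized=True), self._norm(g))
        assert np.allclose(td.db, -30.0)

    def test_tiny_normative_cells_masked(self):
        norm = np.ones((26, 26))
        norm[0, 0] = 1e-9
        td = total_deviation_db(_cm(np.ones((26, 26)), normalized=True),
                                self._norm(norm))
        assert not td.valid[0, 0]
        assert td.valid[1:, 1:].all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_deviation_db(_cm(np.ones((13, 13))), self._norm(np.ones((26, 26))))


class TestCIBoundaries:
    def test_uniform_sample_matches_analytic_percentiles(self):
        rng = np.random.default_rng(123)
        vals = rng.uniform(-1, 1, 10000)
        b = ci_boundaries(vals)
        assert b[90][0] == pytest.approx(-0.9, abs=0.02)
        assert b[90][1] == pytest.approx(+0.9, abs=0.02)

    def test_constant_input_collapses(self):
        b = ci_boundaries(np.full(100, 2.5))
        assert all(lo == hi == 2.5 for lo, hi in b.values())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nesting_of_levels(self, seed):
        vals = np.random.default_rng(seed).normal(size=500)
        b = ci_boundaries(vals)
        assert b[99][0] <= b[96][0] <= b[90][0]
        assert b[90][1] <= b[96][1] <= b[99][1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ci_boundaries(np.array([]))


class TestClassification:
    def _td(self, db):
        db = np.asarray(db, float)
        from vfrecon.reconstruction import TotalDeviationMap
        return TotalDeviationMap(db=db, valid=np.ones_like(db, bool))

    def test_boundary_cell_is_within(self):
        td = self._td([[-2.0, 0.0, 2.0]])
        out = classify_deviation(td, {90: (-2.0, 2.0)})
        assert list(out.labels[0]) == ["within", "within", "within"]

    def test_counts(self):
        db = np.zeros((5, 5))
        db[2, 2] = -5.0
        out = classify_deviation(self._td(db), {90: (-2.7, 1.9)})
        assert (out.labels == "below").sum() == 1
        assert out.labels[2, 2] == "below"

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError):
            classify_deviation(self._td(np.zeros((2, 2))), {96: (-1, 1)})

    def test_masked_cells_labeled_masked(self):
        from vfrecon.reconstruction import TotalDeviationMap
        td = TotalDeviationMap(db=np.zeros((2, 2)),
                               valid=np.array([[True, False], [True, True]]))
        out = classify_deviation(td, {90: (-1.0, 1.0)})
        assert out.labels[0, 1] == "masked"
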