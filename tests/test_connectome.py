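"""Connectivity preprocessing: normalization, imputation, CIB, variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import distwm
from distwm.connectome import (build_connectome, celltype_matrix, cib_matrix,
                               impute_hierarchy, minmax_normalize,
                               normalize_connectivity, read_weight_csv,
                               rescale_connectivity, split_by_target,
                               write_weight_csv)


def _atlas(vol, dens, n=None):
    n = n or len(vol)
    table = pd.DataFrame({
        "name": [f"X{i}" for i in range(n)],
        "volume_mm3": vol, "neuron_density": dens, "pv_density": 0.1,
        "hierarchy_raw": np.linspace(0, 1, n), "module": "m",
        "is_thalamic": False})
    return distwm.AreaAtlas(table)


class TestNormalizeConnectivity:
    def test_volume_scaling_only(self):
        atlas = _atlas([1.0, 2.0], [1.0, 1.0])
        W = normalize_connectivity(np.array([[0.0, 2.0], [3.0, 0.0]]), atlas)
        assert np.allclose(W, [[0.0, 4.0], [3.0, 0.0]])

    def test_identity_case(self):
        atlas = _atlas([1.0] * 3, [1.0] * 3)
        W_raw = np.array([[0, 1, 2], [3, 0, 4], [5, 6, 0.0]])
        assert np.allclose(normalize_connectivity(W_raw, atlas), W_raw)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        W_raw = rng.random((5, 5))
        vol = rng.uniform(0.5, 3, 5)
        dens = rng.uniform(0.5, 3, 5)
        atlas = _atlas(vol, dens)
        W = normalize_connectivity(W_raw, atlas)
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = W_raw[i, j] * vol[j] / dens[i]
        assert np.allclose(W, expected)

    def test_bad_density_names_area(self):
        table = _atlas([1.0, 1.0], [1.0, 1.0]).table.copy()
        table.loc[1, "neuron_density"] = 0.0
        atlas = distwm.AreaAtlas(table)
        with pytest.raises(ValueError, match="X1"):
            normalize_connectivity(np.zeros((2, 2)), atlas)


class TestMinmaxNormalize:
    def test_basic(self):
        assert np.allclose(minmax_normalize([1, 3, 5]), [0, 0.5, 1])

    def test_gaps_pass_through(self):
        out = minmax_normalize([0.2, np.nan, 0.8])
        assert out[0] == 0 and out[2] == 1 and np.isnan(out[1])

    def test_external_bounds_can_exceed_unit_interval(self):
        # thalamic scores normalized with cortical bounds
        out = minmax_normalize([-0.1, 0.5, 1.2], bounds=(0.0, 1.0))
        assert out[0] < 0 and out[2] > 1 and np.isclose(out[1], 0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="range"):
            minmax_normalize([2.0, 2.0, 2.0])


class TestImputeHierarchy:
    def test_single_known_neighbor_closed_form(self):
        W = np.array([[0.0, 3.0], [0.0, 0.0]])
        h = np.array([np.nan, 0.6])
        out = impute_hierarchy(W, h, alpha_h=1.33, beta_h=-0.22)
        assert np.isclose(out[0], 1.33 * 0.6 - 0.22)
        assert out[1] == 0.6

    def test_identity_coefficients_preserve_constant(self):
        W = np.ones((3, 3))
        h = np.array([0.4, 0.4, np.nan])
        out = impute_hierarchy(W, h, alpha_h=1.0, beta_h=0.0)
        assert np.isclose(out[2], 0.4)

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(3)
        W = rng.random((6, 6))
        h = rng.random(6)
        h_gappy = h.copy()
        h_gappy[[1, 4]] = np.nan
        out = impute_hierarchy(W, h_gappy, 1.33, -0.22)
        known = np.isfinite(h_gappy)
        for i in (1, 4):
            expect = 1.33 * (W[i, known] @ h[known]) / W[i, known].sum() - 0.22
            assert np.isclose(out[i], expect)

    def test_isolated_gap_errors(self):
        W = np.zeros((2, 2))
        with pytest.raises(ValueError):
            impute_hierarchy(W, np.array([np.nan, 0.5]))


class TestRescaleConnectivity:
    def test_hand_computed_values(self):
        W = np.array([[0.0, 16.0], [4.0, 0.0]])
        out = rescale_connectivity(W, k_scale=0.5)
        assert np.isclose(out.max(), 1.0)
        assert np.isclose(out[1, 0], 2.0 / 4.0)

    def test_k1_is_max_normalization(self):
        W = np.array([[0.0, 0.5], [0.2, 0.0]])
        assert np.allclose(rescale_connectivity(W, 1.0), W / 0.5)

    def test_range_compression_five_decades(self):
        W = np.array([[0.0, 1e-5], [1.0, 0.0]])
        out = rescale_connectivity(W, 0.3)
        nz = out[out > 0]
        assert np.isclose(np.log10(nz.max() / nz.min()), 5 * 0.3)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            rescale_connectivity(np.zeros((3, 3)), 0.3)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 1.0))
    def test_rank_preserving(self, seed, k):
        W = np.random.default_rng(seed).random((5, 5))
        out = rescale_connectivity(W, k)
        assert np.array_equal(np.argsort(W, axis=None, kind="stable"),
                              np.argsort(out, axis=None, kind="stable"))


class TestCibMatrix:
    def test_equal_hierarchy_gives_half(self):
        m = cib_matrix(np.array([0.3, 0.3]))
        assert np.allclose(m, 0.5)

    def test_unit_difference_closed_form(self):
        m = cib_matrix(np.array([0.0, 1.0]), beta=2.42)
        assert np.isclose(m[1, 0], 1.0 / (1.0 + np.exp(-2.42)))
        assert np.isclose(m[0, 1], 1.0 / (1.0 + np.exp(2.42)))
        assert np.isclose(m[1, 0] + m[0, 1], 1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5))
    def test_complement_and_shift_invariance(self, seed, shift):
        h = np.random.default_rng(seed).random(4)
        m = cib_matrix(h)
        assert np.allclose(m + m.T, 1.0)
        assert np.allclose(cib_matrix(h + shift), m)


class TestSplitAndVariants:
    def test_mean_cib_split_is_half(self):
        W = np.array([[0.0, 1.0], [0.4, 0.0]])
        W_E, W_I = split_by_target(W, np.full((2, 2), 0.5))
        assert np.allclose(W_E, W / 2) and np.allclose(W_I, W / 2)

    def test_split_conservation_random(self):
        rng = np.random.default_rng(5)
        W = rng.random((6, 6))
        m = rng.random((6, 6))
        W_E, W_I = split_by_target(W, m)
        assert np.array_equal(W_E + W_I, W) or np.allclose(W_E + W_I, W, atol=1e-16)

    def test_celltype_pure_feedforward_limit(self):
        W = np.array([[0.0, 0.6], [0.3, 0.0]])
        m = np.ones((2, 2))
        out = celltype_matrix(W, m, PV=np.array([1.0, 1.0]), mode="celltype")
        assert np.allclose(out, W / W.max())

    def test_celltype_row_vanishes_at_m_half_pv_one(self):
        W = np.ones((2, 2)) - np.eye(2)
        m = np.full((2, 2), 0.5)
        out = celltype_matrix(W, m, PV=np.array([1.0, 0.0]), mode="celltype")
        assert np.allclose(out[0], 0.0)      # k_cell = 0.5 - 0.5*1 = 0
        assert out[1, 0] > 0

    def test_sign_only_flips_feedback(self):
        W = np.array([[0.0, 2.0], [3.0, 0.0]])
        m = np.array([[0.5, 0.4], [0.6, 0.5]])
        out = celltype_matrix(W, m, PV=np.zeros(2), mode="sign_only")
        assert out[0, 1] == -2.0 and out[1, 0] == 3.0

    def test_celltype_with_zero_pv_reduces_to_cib_weighting(self):
        # with no PV discount the coefficient is just the CIB feedforwardness
        rng = np.random.default_rng(8)
        W = rng.random((5, 5))
        m = cib_matrix(rng.random(5))
        cell = celltype_matrix(W, m, np.zeros(5), mode="celltype")
        expected = m * W
        assert np.allclose(cell, expected / expected.max())

    def test_celltype_degenerate_normalization_errors(self):
        W = np.ones((2, 2)) - np.eye(2)
        m = np.full((2, 2), 0.1)     # k_cell < 0 everywhere with PV=1
        with pytest.raises(ValueError, match="degenerate"):
            celltype_matrix(W, m, PV=np.ones(2), mode="celltype")


class TestBuildConnectome:
    def test_invariants_on_synthetic(self, default_connectome):
        default_connectome.validate()

    def test_staged_matrices_keep_zero_diagonal(self, default_connectome):
        for M in (default_connectome.W_raw, default_connectome.W_norm,
                  default_connectome.W, default_connectome.W_E,
                  default_connectome.W_I):
            assert np.abs(np.diag(M)).max() == 0

    def test_weight_csv_round_trip(self, toy, tmp_path):
        _, W_raw, conn = toy
        path = tmp_path / "w.csv"
        write_weight_csv(path, W_raw, conn.names, stage="raw")
        W2, names = read_weight_csv(path)
        assert names == conn.names
        assert np.allclose(W2, W_raw)
        assert (tmp_path / "w.csv.meta.json").exists()
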