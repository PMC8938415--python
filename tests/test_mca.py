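"""Maximum covariance analysis: oracles, gap handling, invariances."""

import numpy as np
import pandas as pd
import pytest

import meltflux as mf
from meltflux.errors import DegenerateInputError
from meltflux.mca import AnomalyField

YEARS = np.arange(2004, 2020)


def _field(values, variable="a", month=6, sites=None):
    values = np.asarray(values, dtype=float)
    sites = sites or [f"S{i}" for i in range(values.shape[1])]
    return AnomalyField(variable, month, YEARS[:values.shape[0]], sites, values)


def brute_force_cross_cov(A, B, min_overlap=3):
    """Loop-over-pairs pairwise-complete covariance (independent oracle)."""
    out = np.zeros((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            a, b = A[:, i], B[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= max(min_overlap, 2):
                out[i, j] = np.cov(a[ok], b[ok], ddof=1)[0, 1]
    return out


class TestBuildField:
    def test_complete_table_shape(self, complete_world):
        monthly = complete_world[4]
        f = mf.build_field(monthly, "gpp", 6, range(2004, 2020))
        assert f.values.shape == (16, 11)
        assert np.isfinite(f.values).all()

    def test_sparse_site_dropped(self, complete_world):
        monthly = complete_world[4].copy()
        first = monthly["site_id"].iloc[0]
        keep_years = monthly[monthly.site_id == first]["year"].unique()[:2]
        drop = (monthly.site_id == first) & ~monthly.year.isin(keep_years)
        monthly = monthly[~drop]
        f = mf.build_field(monthly, "gpp", 6, range(2004, 2020))
        assert first not in f.site_ids

    def test_empty_year_range_rejected(self, complete_world):
        with pytest.raises(DegenerateInputError):
            mf.build_field(complete_world[4], "gpp", 6, [])


class TestCrossCovariance:
    def test_complete_data_equals_textbook(self):
        rng = np.random.default_rng(0)
        A, B = rng.standard_normal((16, 5)), rng.standard_normal((16, 4))
        C, n_ov = mf.cross_covariance(_field(A), _field(B, "b"))
        Ac, Bc = A - A.mean(0), B - B.mean(0)
        np.testing.assert_allclose(C, Ac.T @ Bc / 15, atol=1e-12)
        assert (n_ov == 16).all()

    def test_gappy_matches_brute_force(self):
        rng = np.random.default_rng(1)
        A, B = rng.standard_normal((16, 6)), rng.standard_normal((16, 5))
        A[rng.random(A.shape) < 0.25] = np.nan
        B[rng.random(B.shape) < 0.25] = np.nan
        C, _ = mf.cross_covariance(_field(A), _field(B, "b"), min_overlap=3)
        np.testing.assert_allclose(C, brute_force_cross_cov(A, B), atol=1e-12)

    def test_constant_column_gives_zero_row(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((10, 3))
        A[:, 0] = 5.0
        C, _ = mf.cross_covariance(_field(A), _field(rng.standard_normal((10, 3)), "b"))
        np.testing.assert_allclose(C[0], 0.0, atol=1e-12)

    def test_no_shared_years_rejected(self):
        a = AnomalyField("a", 6, [2000, 2001, 2002], ["x", "y"],
                         np.ones((3, 2)))
        b = AnomalyField("b", 6, [2010, 2011, 2012], ["x", "y"],
                         np.ones((3, 2)))
        with pytest.raises(DegenerateInputError):
            mf.cross_covariance(a, b)


class TestRunMca:
    def test_rank_one_pair_gives_scf_one(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(16)
        A = np.outer(base, rng.uniform(0.5, 2.0, 5))
        B = np.outer(base, rng.uniform(0.5, 2.0, 4))
        res = mf.run_mca(_field(A), _field(B, "b"))
        assert res.scf[0] == pytest.approx(1.0, abs=1e-12)

    def test_complete_data_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(4)
        A, B = rng.standard_normal((16, 11)), rng.standard_normal((16, 11))
        res = mf.run_mca(_field(A), _field(B, "b"))
        C = (A - A.mean(0)).T @ (B - B.mean(0)) / 15
        s_ref = np.linalg.svd(C, compute_uv=False)
        np.testing.assert_allclose(res.singular_values, s_ref, atol=1e-10)
        # loadings orthonormal
        np.testing.assert_allclose(res.left_loadings.T @ res.left_loadings,
                                   np.eye(11), atol=1e-10)
        np.testing.assert_allclose(res.right_loadings.T @ res.right_loadings,
                                   np.eye(11), atol=1e-10)

    def test_scf_sums_to_one_and_sorted(self):
        rng = np.random.default_rng(5)
        res = mf.run_mca(_field(rng.standard_normal((16, 7))),
                         _field(rng.standard_normal((16, 6)), "b"))
        assert res.scf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(res.singular_values) <= 1e-12).all()
        assert (res.singular_values >= 0).all()

    def test_sign_convention_largest_left_loading_positive(self):
        rng = np.random.default_rng(6)
        res = mf.run_mca(_field(rng.standard_normal((16, 5))),
                         _field(rng.standard_normal((16, 5)), "b"))
        for k in range(res.left_loadings.shape[1]):
            col = res.left_loadings[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_site_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        A, B = rng.standard_normal((16, 6)), rng.standard_normal((16, 5))
        perm = rng.permutation(6)
        res = mf.run_mca(_field(A), _field(B, "b"))
        res_p = mf.run_mca(_field(A[:, perm],
                                  sites=[f"S{i}" for i in perm]),
                           _field(B, "b"))
        np.testing.assert_allclose(res_p.singular_values,
                                   res.singular_values, atol=1e-10)
        np.testing.assert_allclose(res_p.scf, res.scf, atol=1e-12)
        np.testing.assert_allclose(res_p.left_loadings, res.left_loadings[perm],
                                   atol=1e-10)

    def test_all_zero_covariance_flagged_undefined(self):
        a = _field(np.full((10, 3), 2.0))
        b = _field(np.full((10, 3), 5.0), "b")
        res = mf.run_mca(a, b)
        assert res.undefined
        assert res.scf is None
        assert res.scf1 is None

    def test_zero_fill_alternative_runs(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((16, 5))
        A[rng.random(A.shape) < 0.2] = np.nan
        res = mf.run_mca(_field(A), _field(rng.standard_normal((16, 4)), "b"),
                         gap_method="zero_fill")
        assert res.scf.sum() == pytest.approx(1.0, abs=1e-12)


class TestScfTable:
    def test_single_result_row(self):
        rng = np.random.default_rng(9)
        res = mf.run_mca(_field(rng.standard_normal((16, 4))),
                         _field(rng.standard_normal((16, 4)), "b"))
        table = mf.scf_table({("a-b", 6): res})
        assert table.iloc[0]["scf1"] == pytest.approx(res.scf[0])
        assert not table.iloc[0]["undefined"]

    def test_undefined_result_marked_not_zero(self):
        res = mf.run_mca(_field(np.full((10, 3), 1.0)),
                         _field(np.full((10, 3), 1.0), "b"))
        table = mf.scf_table({("a-b", 6): res})
        assert table.iloc[0]["undefined"]
        assert np.isnan(table.iloc[0]["scf1"])

    def test_coupled_fields_beat_white_noise(self, balanced_world):
        """Snowmelt-coupled June GPP shows a stronger first mode than noise."""
        _, _, _, _, monthly, melt = balanced_world
        years = range(2004, 2020)
        coupled = mf.run_mca(mf.build_field(monthly, "gpp", 6, years),
                             mf.build_snowmelt_field(melt, years, month=6))
        rng = np.random.default_rng(0)
        noise_scf = [
            mf.run_mca(_field(rng.standard_normal((16, 11))),
                       _field(rng.standard_normal((16, 11)), "b")).scf1
            for _ in range(20)]
        assert coupled.scf1 > np.mean(noise_scf)
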