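import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opticpath import VoxelGrid
from opticpath.compartments import CompartmentFractions
from opticpath.geometry import bin_segments, partition_rois
from opticpath.masking import DensityMap, TractMask
from opticpath.stats import (
    clinical_correlate,
    group_compare,
    hochberg,
    segment_means,
    slice_profile,
    welch_from_summary,
)
from opticpath.tensor import ScalarMaps, validity_mask


def brute_force_hochberg(p, alpha=0.05):
    """Independent oracle: test every k directly, largest first."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sp = p[order]
    reject = np.zeros(m, dtype=bool)
    for k in range(m, 0, -1):
        if sp[k - 1] <= alpha / (m - k + 1):
            reject[order[:k]] = True
            break
    return reject


@pytest.fixture
def grid():
    return VoxelGrid(dims=(6, 12, 6), voxel_size=2.0, ap_axis=1)


def scalar_maps(fa, md):
    maps = ScalarMaps(fa=fa, md=md, valid=np.zeros(fa.shape, dtype=bool))
    return ScalarMaps(fa=fa, md=md, valid=validity_mask(maps))


def uniform_inputs(grid, fa=0.4, md=1.5e-3, nwm=0.3, ngm=0.4, ncsf=0.2):
    shape = grid.shape
    maps = scalar_maps(np.full(shape, fa), np.full(shape, md))
    bg = 1.0 - nwm - ngm - ncsf
    fr = CompartmentFractions(
        np.full(shape, nwm), np.full(shape, ngm), np.full(shape, ncsf), np.full(shape, bg)
    )
    density = DensityMap(np.ones(shape, dtype=int), grid)
    mask = TractMask(np.ones(shape, dtype=bool), grid)
    return maps, fr, density, mask


class TestSliceProfile:
    def test_constant_field(self, grid):
        prof = slice_profile(*uniform_inputs(grid, fa=0.4))
        assert np.allclose(prof["fa"], 0.4)
        assert np.allclose(prof["nwm"], 0.3)

    def test_invalid_fa_excluded_from_mean(self, grid):
        maps, fr, density, mask = uniform_inputs(grid, fa=0.4)
        fa = maps.fa.copy()
        fa[0, 3, 0] = 1.0  # FA = 1 fails the open-interval rule
        maps = scalar_maps(fa, maps.md)
        prof = slice_profile(maps, fr, density, mask)
        assert prof.loc[prof.slice_index == 3, "fa"].item() == pytest.approx(0.4)

    def test_fraction_mean_keeps_fa_invalid_voxels(self, grid):
        maps, fr, density, mask = uniform_inputs(grid)
        fa = maps.fa.copy()
        fa[:, 4, :] = 1.5  # whole slice FA-invalid
        maps = scalar_maps(fa, maps.md)
        prof = slice_profile(maps, fr, density, mask)
        row = prof[prof.slice_index == 4]
        assert np.isnan(row["fa"].item())
        assert row["nwm"].item() == pytest.approx(0.3)

    def test_arithmetic_mean_of_fractions(self, grid):
        maps, fr, density, mask = uniform_inputs(grid)
        nwm = fr.nwm.copy()
        nwm[:, 5, :] = 0.0
        nwm[0:2, 5, 0] = [0.2, 0.4]
        nwm[0, 5, 1] = 0.6
        m = np.zeros(grid.shape, dtype=bool)
        m[0:2, 5, 0] = True
        m[0, 5, 1] = True
        m[0, 0, 0] = True  # keep another slice populated
        fr2 = CompartmentFractions(nwm, fr.ngm, fr.ncsf, fr.nbg)
        prof = slice_profile(maps, fr2, density, TractMask(m, grid))
        assert prof.loc[prof.slice_index == 5, "nwm"].item() == pytest.approx(0.4)

    def test_empty_mask_errors(self, grid):
        maps, fr, density, _ = uniform_inputs(grid)
        with pytest.raises(ValueError, match="empty"):
            slice_profile(maps, fr, density, TractMask(np.zeros(grid.shape, bool), grid))

    def test_empty_slice_yields_nan(self, grid):
        maps, fr, density, _ = uniform_inputs(grid)
        m = np.ones(grid.shape, dtype=bool)
        m[:, 6, :] = False
        prof = slice_profile(maps, fr, density, TractMask(m, grid))
        assert np.isnan(prof.loc[prof.slice_index == 6, "fa"].item())


class TestSegmentMeans:
    def _segments(self, grid):
        mask = TractMask(np.ones(grid.shape, dtype=bool), grid)
        return bin_segments(mask, lgn_mm=22.0, chiasm_mm=12.0, orbit_mm=5.0,
                            n_post=2, n_pre=1)

    def _profile(self, slice_rows):
        cols = ["slice_index", "n_voxels", "fa", "md", "ncsf", "ngm", "nwm"]
        return pd.DataFrame(slice_rows, columns=cols)

    def test_equal_weights(self, grid):
        segs = self._segments(grid)
        post_slices = [s for s, g in segs.segment_of_slice.items() if g == 1]
        rows = [[s, 10, v, 1e-3, 0.2, 0.3, 0.5] for s, v in zip(post_slices, [0.3, 0.5])]
        out = segment_means(self._profile(rows), segs)
        assert out.loc[(out.level == "segment") & (out["item"] == 1), "fa"].item() == pytest.approx(0.4)

    def test_voxel_count_weighting(self, grid):
        segs = self._segments(grid)
        post_slices = [s for s, g in segs.segment_of_slice.items() if g == 1]
        rows = [
            [post_slices[0], 30, 0.3, 1e-3, 0.2, 0.3, 0.5],
            [post_slices[1], 10, 0.5, 1e-3, 0.2, 0.3, 0.5],
        ]
        out = segment_means(self._profile(rows), segs)
        # (0.3 * 30 + 0.5 * 10) / 40 = 0.35
        assert out.loc[(out.level == "segment") & (out["item"] == 1), "fa"].item() == pytest.approx(0.35)

    def test_all_missing_slices_propagate_nan(self, grid):
        segs = self._segments(grid)
        rows = [[s, 0, np.nan, np.nan, np.nan, np.nan, np.nan]
                for s in segs.segment_of_slice]
        out = segment_means(self._profile(rows), segs)
        assert out["fa"].isna().all()

    def test_invariant_to_slice_splitting(self, grid):
        # splitting one slice into two pseudo-slices with the same voxels
        # leaves the weighted segment mean unchanged
        segs = self._segments(grid)
        s0, s1 = [s for s, g in segs.segment_of_slice.items() if g == 1][:2]
        whole = self._profile([[s0, 20, 0.42, 1e-3, 0.2, 0.3, 0.5],
                               [s1, 0, np.nan] + [np.nan] * 4])
        split = self._profile([[s0, 8, 0.42, 1e-3, 0.2, 0.3, 0.5],
                               [s1, 12, 0.42, 1e-3, 0.2, 0.3, 0.5]])
        a = segment_means(whole, segs)
        b = segment_means(split, segs)
        assert a.loc[0, "fa"] == pytest.approx(b.loc[0, "fa"])


class TestWelch:
    def test_null_identity(self):
        res = welch_from_summary(0.5, 0.1, 10, 0.5, 0.2, 12)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry_and_p_invariance(self):
        a = welch_from_summary(0.3, 0.05, 8, 0.4, 0.07, 13)
        b = welch_from_summary(0.4, 0.07, 13, 0.3, 0.05, 8)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)
        assert a.df == pytest.approx(b.df)

    def test_against_scipy(self):
        from scipy.stats import ttest_ind_from_stats

        res = welch_from_summary(0.291, 0.019, 8, 0.392, 0.043, 13)
        ref = ttest_ind_from_stats(0.291, 0.019, 8, 0.392, 0.043, 13, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_from_summary(0.1, 0.1, 1, 0.2, 0.1, 5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_from_summary(0.1, 0.0, 5, 0.2, 0.0, 5)


class TestHochberg:
    def test_all_ones_rejects_nothing(self):
        assert not hochberg([1.0, 1.0, 1.0]).any()

    def test_hand_traced_all_rejected(self):
        # k = 4: p(4) = 0.04 <= 0.05 / 1
        flags = hochberg([0.001, 0.02, 0.03, 0.04])
        assert flags.all()

    def test_hand_traced_none_rejected(self):
        # 0.9 > 0.05 and 0.04 > 0.05/2 = 0.025 -> no k works
        flags = hochberg([0.04, 0.9])
        assert not flags.any()

    def test_empty_input(self):
        assert hochberg([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            hochberg([0.5, 1.5])

    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=8),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, grid_points, alpha):
        p = np.array(grid_points) / 100.0
        np.testing.assert_array_equal(hochberg(p, alpha), brute_force_hochberg(p, alpha))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_dominates_bonferroni(self, pvals):
        p = np.array(pvals)
        bonf = p <= 0.05 / p.size
        hoch = hochberg(p, 0.05)
        assert (bonf <= hoch).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 12))
            ref = multipletests(p, alpha=0.05, method="simes-hochberg")[0]
            np.testing.assert_array_equal(hochberg(p, 0.05), ref)


def cohort_frame(rng, n1=8, n2=13, items=("a", "b"), delta=0.0):
    rows = []
    for group, n, shift in (("patient", n1, delta), ("control", n2, 0.0)):
        for i in range(n):
            for item in items:
                rows.append(
                    {
                        "subject": f"{group}{i}",
                        "group": group,
                        "item": item,
                        "variable": "fa",
                        "value": rng.normal(shift, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_data_nothing_rejected(self, rng):
        df = cohort_frame(rng, n1=6, n2=6)
        # mirror group 1 into group 2 so the data are identical
        g1 = df[df.group == "patient"].copy()
        g2 = g1.copy()
        g2["group"] = "control"
        g2["subject"] = g2["subject"] + "c"
        table = group_compare(pd.concat([g1, g2]), "patient", "control")
        assert np.allclose(table["t"], 0.0)
        assert not table["fwe_reject"].any()

    def test_small_group_errors(self, rng):
        df = cohort_frame(rng, n1=1, n2=5)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            group_compare(df, "patient", "control")

    def test_family_size_recorded(self, rng):
        df = cohort_frame(rng, items=tuple("abcde"))
        table = group_compare(df, "patient", "control")
        assert (table["family_size"] == 5).all()

    def test_familywise_error_controlled_under_null(self, rng):
        # 400 null families of 5 tests: P(any rejection) should be <= alpha
        n_reject = 0
        for _ in range(400):
            pvals = []
            for _ in range(5):
                x1 = rng.normal(0, 1, 8)
                x2 = rng.normal(0, 1, 13)
                pvals.append(
                    welch_from_summary(
                        x1.mean(), x1.std(ddof=1), 8, x2.mean(), x2.std(ddof=1), 13
                    ).p
                )
            n_reject += hochberg(pvals, 0.05).any()
        # 0.05 plus three binomial standard errors
        assert n_reject / 400 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_high_power_case_rejected(self, rng):
        # patient/control separated by ~3 pooled sds: rejection expected
        hits = 0
        for _ in range(20):
            df = cohort_frame(rng, delta=3.0)
            table = group_compare(df, "patient", "control")
            hits += bool(table["fwe_reject"].all())
        assert hits >= 18


class TestClinicalCorrelate:
    def _stats(self, values, item="optic_nerve/L"):
        return pd.DataFrame(
            {
                "subject": [f"P{i:03d}" for i in range(len(values))],
                "group": "patient",
                "item": item,
                "variable": "nwm",
                "value": values,
            }
        )

    def _clinical(self, rng, n, va_left=None):
        rows = []
        for i in range(n):
            for eye in ("left", "right"):
                va = va_left[i] if (va_left is not None and eye == "left") else rng.normal(1.7, 0.3)
                rows.append(
                    {
                        "subject": f"P{i:03d}",
                        "eye": eye,
                        "va_logmar": va,
                        "rnfl_um": rng.uniform(40, 110),
                        "rnfl_temporal_um": rng.uniform(40, 110),
                        "rnfl_nasal_um": rng.uniform(40, 110),
                        "duration_days": rng.integers(30, 900),
                        "affected_order": "first" if eye == "left" else "second",
                    }
                )
        return pd.DataFrame(rows)

    def test_perfectly_linear_covariate(self, rng):
        vals = np.linspace(0.1, 0.3, 12)
        clinical = self._clinical(rng, 12, va_left=2.0 * vals + 0.5)
        out = clinical_correlate(self._stats(vals), clinical)
        row = out[(out["item"] == "optic_nerve/L") & (out.covariate == "va_logmar")]
        assert row["r"].item() == pytest.approx(1.0)
        assert row["eye_mapping"].item() == "ipsilateral/left"

    def test_independent_covariate_near_zero(self, rng):
        n = 1000
        vals = rng.normal(0.2, 0.05, n)
        clinical = self._clinical(rng, n)
        out = clinical_correlate(self._stats(vals), clinical)
        row = out[(out["item"] == "optic_nerve/L") & (out.covariate == "va_logmar")]
        assert abs(row["r"].item()) < 0.1

    def test_insufficient_pairs_reported(self, rng):
        vals = np.array([0.1, 0.2])
        clinical = self._clinical(rng, 2)
        out = clinical_correlate(self._stats(vals), clinical)
        row = out[(out["item"] == "optic_nerve/L") & (out.covariate == "va_logmar")]
        assert np.isnan(row["r"].item())
        assert "pairs" in row["reason"].item()

    def test_affected_order_mapping_used_for_tract(self, rng):
        vals = np.linspace(0.1, 0.3, 10)
        clinical = self._clinical(rng, 10)
        out = clinical_correlate(self._stats(vals, item="optic_tract/L"), clinical)
        mappings = set(out[out["item"] == "optic_tract/L"]["eye_mapping"])
        assert {"affected/first", "affected/second"} <= mappings
        assert "quadrants/left" in mappings
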