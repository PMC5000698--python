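import numpy as np
import pytest

from silkpol.fdh import (
    ElementMoments,
    MomentSet,
    WashSeries,
    anisotropy_difference,
    central_moments,
    compute_fdh,
    derived_params,
    moment_set_from_image,
    series_report,
)
from silkpol.synthetic import SyntheticImageSpec, generate_synthetic_image
from silkpol.tables import load_paper_table


def loop_moment_oracle(values):
    """Brute-force loop sums for P1..P4 (population denominators)."""
    n = len(values)
    mu = sum(values) / n
    var = sum((v - mu) ** 2 for v in values) / n
    sd = var**0.5
    p3 = sum((v - mu) ** 3 for v in values) / n / sd**3
    p4 = sum((v - mu) ** 4 for v in values) / n / sd**4
    return mu, var, p3, p4


class TestComputeFdh:
    def test_constant_plane_single_bin(self):
        fdh = compute_fdh(np.full((10, 10), 0.3), "m22")
        assert fdh.area == pytest.approx(1.0, abs=1e-12)
        assert (fdh.density > 0).sum() == 1
        k = np.argmax(fdh.density)
        assert fdh.bin_edges[k] <= 0.3 <= fdh.bin_edges[k + 1]

    def test_uniform_law_oracle(self):
        rng = np.random.default_rng(11)
        n = 1_000_000
        vals = rng.uniform(-1.0, 1.0, n)
        fdh = compute_fdh(vals, "m23", n_bins=400, value_range=(-1.0, 1.0))
        p = 1.0 / 400
        se_density = np.sqrt(n * p * (1 - p)) / (n * 2.0 / 400)
        assert np.abs(fdh.density - 0.5).max() <= 5 * se_density

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_area_normalized_to_1e9(self, seed):
        rng = np.random.default_rng(seed)
        fdh = compute_fdh(rng.normal(0.2, 0.4, (64, 64)), "m22")
        assert abs(fdh.area - 1.0) <= 1e-9

    def test_out_of_range_clipped_and_counted(self):
        vals = np.array([[-5.0, 0.0], [0.5, 7.0]])
        fdh = compute_fdh(vals, "m11", value_range=(-1.0, 1.0))
        assert fdh.n_clipped == 2
        assert abs(fdh.area - 1.0) <= 1e-12
        assert fdh.density[0] > 0 and fdh.density[-1] > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            compute_fdh(np.ones((4, 4)), "m11", mask=np.zeros((4, 4), bool))

    def test_histogram_uses_400_parts(self):
        fdh = compute_fdh(np.zeros((8, 8)), "m11")
        assert fdh.density.size == 400 and fdh.bin_edges.size == 401


class TestCentralMoments:
    def test_constant_plane_flags_undefined(self):
        m = central_moments(np.full((5, 5), 2.5))
        assert m.p1 == 2.5 and m.p2 == 0.0
        assert m.p3 is None and m.p4 is None

    def test_symmetric_two_point_closed_form(self):
        vals = np.array([-0.4, 0.4] * 50)
        m = central_moments(vals)
        assert m.p1 == pytest.approx(0.0, abs=1e-15)
        assert m.p2 == pytest.approx(0.16)
        assert m.p3 == pytest.approx(0.0, abs=1e-12)
        assert m.p4 == pytest.approx(1.0)

    def test_gaussian_against_loop_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.5, 0.1, 100_000)
        m = central_moments(vals)
        mu, var, p3, p4 = loop_moment_oracle(list(vals))
        assert m.p1 == pytest.approx(mu, abs=1e-12)
        assert m.p2 == pytest.approx(var, abs=1e-12)
        assert m.p3 == pytest.approx(p3, abs=1e-12)
        assert m.p4 == pytest.approx(p4, abs=1e-12)
        # and the Gaussian limits within 5 standard errors
        n = vals.size
        assert abs(m.p1 - 0.5) < 5 * 0.1 / np.sqrt(n)
        assert abs(m.p2 - 0.01) < 5 * 0.01 * np.sqrt(2.0 / n)
        assert abs(m.p3) < 5 * np.sqrt(6.0 / n)
        assert abs(m.p4 - 3.0) < 5 * np.sqrt(24.0 / n)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            central_moments(np.array([1.0]))

    def test_binning_invariance_of_low_moments(self):
        """P1/P2 from the 400-bin FDH agree with raw-pixel moments to
        within one bin width."""
        rng = np.random.default_rng(9)
        vals = rng.normal(0.3, 0.15, 50_000).clip(-1, 1)
        raw = central_moments(vals)
        fdh = compute_fdh(vals, "m22")
        w = np.diff(fdh.bin_edges)
        p1_fdh = float((fdh.bin_centers * fdh.density * w).sum())
        p2_fdh = float(((fdh.bin_centers - p1_fdh) ** 2 * fdh.density * w).sum())
        bin_width = w[0]
        assert abs(p1_fdh - raw.p1) < bin_width
        assert abs(p2_fdh - raw.p2) < bin_width


class TestDerivedParams:
    def test_wash_zero_is_reference(self):
        series = load_paper_table("F")
        d = derived_params(series, 0)
        assert d.d22p1 == 0.0 and d.d23p2 == 0.0

    def test_table1_wash0_c1p1(self):
        # (0.536 - 0.039) / 0.536
        d = derived_params(load_paper_table("F"), 0)
        assert d.c1p1 == pytest.approx((0.536 - 0.039) / 0.536, abs=1e-12)
        assert 0.9 < d.c1p1 < 0.95

    def test_table3_wash6_d22p1_negative(self):
        # (0.307 - 0.560) / 0.560
        d = derived_params(load_paper_table("T"), 6)
        assert d.d22p1 == pytest.approx((0.307 - 0.560) / 0.560, abs=1e-12)
        assert d.d22p1 < 0

    def test_toilet_soap_d22p1_always_negative(self):
        series = load_paper_table("T")
        assert all(d.d22p1 < 0 for d in series.derived()[1:])

    def test_zero_denominator_names_element(self):
        ms = MomentSet(moments={
            "m22": ElementMoments(0.0, 0.1), "m33": ElementMoments(0.1, 0.1),
            "m23": ElementMoments(0.0, 0.1),
        })
        series = WashSeries(detergent_label="x", moments=[ms, ms])
        with pytest.raises(ZeroDivisionError, match="m22 P1"):
            derived_params(series, 1)

    def test_missing_wash_index(self):
        with pytest.raises(IndexError, match="wash 9"):
            derived_params(load_paper_table("F"), 9)


class TestAnisotropyDifference:
    @pytest.mark.parametrize(
        "detergent,wash,expected",
        [("F", 0, 0.497), ("T", 0, 0.521)],
    )
    def test_printed_values(self, detergent, wash, expected):
        series = load_paper_table(detergent)
        assert anisotropy_difference(series.moments[wash]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_equal_means_give_zero(self):
        ms = MomentSet(moments={"m22": ElementMoments(0.3, 0.0),
                                "m33": ElementMoments(0.3, 0.0)})
        assert anisotropy_difference(ms) == 0.0


class TestSeriesReport:
    def test_color_stain_net_bounds(self):
        r = series_report(load_paper_table("C"))
        assert r["m22_p2_fold"].iloc[6] == pytest.approx(0.107 / 0.024, abs=1e-12)
        assert r["m22_p2_fold"].iloc[6] > 4
        assert r["abs_dP1_m12"].max() == pytest.approx(0.024, abs=1e-12)
        assert r["abs_dP1_m12"].max() > 0.02

    def test_static_series_all_zero_derived(self):
        ms = MomentSet(moments={
            "m22": ElementMoments(0.5, 0.02), "m33": ElementMoments(0.04, 0.02),
            "m23": ElementMoments(0.01, 0.02),
        })
        series = WashSeries(detergent_label="static", moments=[ms] * 4)
        r = series_report(series)
        assert (r["d22p1"] == 0).all() and (r["d23p2"] == 0).all()
        assert r["c1p1"].nunique() == 1


class TestMomentRecovery:
    def test_synthetic_image_targets_within_5_se(self):
        means = {"m22": 0.5, "m33": 0.04, "m23": 0.01}
        variances = {"m22": 0.02, "m33": 0.015, "m23": 0.018}
        spec = SyntheticImageSpec(
            means=means, variances=variances, shape=(320, 320), seed=21
        )
        momset = moment_set_from_image(generate_synthetic_image(spec))
        n = 320 * 320
        for el in means:
            m = momset[el]
            se_mean = np.sqrt(variances[el] / n)
            se_var = variances[el] * np.sqrt(2.0 / n)
            assert abs(m.p1 - means[el]) < 5 * se_mean
            assert abs(m.p2 - variances[el]) < 5 * se_var
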