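"""EQD2, Niemierko EUD, Poisson-LQ TCP and LKB NTCP against independent oracles."""

import math

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.optimize import brentq

from planeval import (
    DoseVolumeHistogram,
    PlanContext,
    effective_dose,
    eqd,
    eud,
    ntcp_lkb,
    tcp_poisson_lq,
    tissue_for_structure,
)
from planeval.exceptions import DomainError, ParameterError
from planeval.radbio import TissueParameters


def physical_dose_for_eqd(target_eqd: float, plan: PlanContext, alpha_beta: float = 4.0) -> float:
    """Invert the EQD transform numerically (independent of the forward path)."""
    if target_eqd == 0:
        return 0.0
    return brentq(
        lambda d: d * (alpha_beta + d / plan.n_fractions) / (alpha_beta + 2) - target_eqd,
        0.0, 200.0, xtol=1e-13,
    )


def dvh_with_eqds(eqds, fracs, plan: PlanContext, name="s"):
    """Differential DVH whose bin-center EQDs are exactly the requested values."""
    doses = np.array([physical_dose_for_eqd(e, plan) for e in eqds])
    order = np.argsort(doses)
    doses, fracs = doses[order], np.asarray(fracs, float)[order]
    edges = np.sort(np.concatenate([doses - 1e-4, doses + 1e-4]))
    fr = np.zeros(edges.size - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    for d, f in zip(doses, fracs):
        fr[np.argmin(np.abs(centers - d))] = f
    return DoseVolumeHistogram(name, edges, fr, 100.0)


class TestEqd:
    def test_2gy_per_fraction_is_identity(self):
        assert eqd(50.0, 25, 4.0) == pytest.approx(50.0, abs=1e-12)

    def test_hf_hand_arithmetic(self):
        # 42.56 Gy in 16 fx: 42.56 * (4 + 2.66) / 6
        assert eqd(42.56, 16, 4.0) == pytest.approx(42.56 * (4 + 42.56 / 16) / 6, abs=1e-12)
        assert eqd(42.56, 16, 4.0) == pytest.approx(47.2416, abs=1e-9)

    def test_zero_dose(self):
        assert eqd(0.0, 16, 4.0) == 0.0

    def test_strictly_increasing_in_dose(self):
        doses = np.linspace(0, 80, 50)
        out = eqd(doses, 16, 4.0)
        assert np.all(np.diff(out) > 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            eqd(-1.0, 16, 4.0)


class TestEud:
    def test_uniform_dose_equals_its_eqd(self, cf_plan, hf_plan, tissue):
        for plan in (cf_plan, hf_plan):
            d = DoseVolumeHistogram.uniform(plan.total_dose, "PTV")
            expected = eqd(d.bin_centers[0], plan.n_fractions, 4.0)
            assert eud(d, plan, tissue["breast_ptv"]) == pytest.approx(expected, rel=1e-12)

    def test_two_bin_cold_spot_dominates(self, cf_plan, tissue):
        d = dvh_with_eqds([40.0, 50.0], [0.5, 0.5], cf_plan)
        # brute-force generalized mean, plain python
        a = -7.2
        expected = (0.5 * 40.0**a + 0.5 * 50.0**a) ** (1 / a)
        result = eud(d, cf_plan, tissue["breast_ptv"])
        assert result == pytest.approx(expected, rel=1e-9)
        assert result == pytest.approx(42.94, abs=0.01)
        assert result < 45.0  # below the arithmetic mean: cold spot dominates

    def test_a_of_one_is_arithmetic_mean(self, cf_plan):
        d = dvh_with_eqds([40.0, 50.0], [0.5, 0.5], cf_plan)
        params = TissueParameters(organ="x", alpha_beta=4.0, a_exponent=1.0)
        assert eud(d, cf_plan, params) == pytest.approx(45.0, rel=1e-9)

    def test_large_negative_a_approaches_min(self, cf_plan):
        d = dvh_with_eqds([40.0, 50.0, 55.0], [0.3, 0.4, 0.3], cf_plan)
        params = TissueParameters(organ="x", alpha_beta=4.0, a_exponent=-100.0)
        assert eud(d, cf_plan, params) == pytest.approx(40.0, abs=0.5)

    def test_zero_dose_bin_with_negative_a_warns_and_returns_zero(self, cf_plan, tissue):
        d = dvh_with_eqds([0.0, 50.0], [0.1, 0.9], cf_plan)
        with pytest.warns(UserWarning, match="zero-dose"):
            assert eud(d, cf_plan, tissue["breast_ptv"]) == 0.0

    def test_dose_floor_recovers_finite_eud(self, cf_plan, tissue):
        d = dvh_with_eqds([0.0, 50.0], [0.1, 0.9], cf_plan)
        val = eud(d, cf_plan, tissue["breast_ptv"], dose_floor=1e-6)
        assert 0 < val < 50.0

    def test_missing_exponent_rejected(self, cf_plan, tissue):
        d = DoseVolumeHistogram.uniform(50.0)
        with pytest.raises(ParameterError):
            eud(d, cf_plan, tissue["heart"])


class TestTcp:
    def test_half_at_d50(self, cf_plan, tissue):
        d_phys = physical_dose_for_eqd(30.89, cf_plan)
        d = DoseVolumeHistogram.uniform(d_phys, "PTV")
        assert tcp_poisson_lq(d, cf_plan, tissue["breast_ptv"]) == pytest.approx(0.5, abs=1e-9)

    def test_uniform_50gy_eqd_brute_force(self, cf_plan, tissue):
        d = dvh_with_eqds([50.0], [1.0], cf_plan)
        # independent evaluation of the per-voxel response
        e_gamma = math.e * 1.3
        expected = math.exp(-math.exp(e_gamma - (50.0 / 30.89) * (e_gamma - math.log(math.log(2)))))
        result = tcp_poisson_lq(d, cf_plan, tissue["breast_ptv"])
        assert result == pytest.approx(expected, rel=1e-9)
        assert result == pytest.approx(0.940, abs=0.001)

    def test_multi_bin_is_weighted_product(self, cf_plan, tissue):
        d = dvh_with_eqds([45.0, 50.0, 55.0], [0.2, 0.5, 0.3], cf_plan)
        e_gamma = math.e * 1.3
        lnln2 = math.log(math.log(2))
        expected = 1.0
        for e, v in zip([45.0, 50.0, 55.0], [0.2, 0.5, 0.3]):
            expected *= math.exp(-math.exp(e_gamma - (e / 30.89) * (e_gamma - lnln2))) ** v
        assert tcp_poisson_lq(d, cf_plan, tissue["breast_ptv"]) == pytest.approx(expected, rel=1e-9)

    def test_zero_dose_nearly_zero(self, cf_plan, tissue):
        d = DoseVolumeHistogram.uniform(0.0, "PTV")
        result = tcp_poisson_lq(d, cf_plan, tissue["breast_ptv"])
        assert result == pytest.approx(math.exp(-math.exp(math.e * 1.3)), rel=1e-9)
        assert result < 1e-14

    def test_monotone_under_dose_scaling(self, cf_plan, tissue, random_dvh):
        base = random_dvh(n_bins=20, seed=4, bin_width=0.5, start=40.0)
        values = []
        for scale in (0.8, 0.9, 1.0, 1.1, 1.2):
            scaled = DoseVolumeHistogram(
                "s", base.bin_edges * scale, base.volume_fraction, base.absolute_volume
            )
            values.append(tcp_poisson_lq(scaled, cf_plan, tissue["breast_ptv"]))
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)


class TestEffectiveDoseAndNtcp:
    def test_uniform_deff_is_that_eqd_any_n(self, cf_plan):
        for n in (0.1, 0.35, 0.87, 1.0):
            params = TissueParameters(organ="x", alpha_beta=4.0, n_volume=n)
            d_phys = physical_dose_for_eqd(30.0, cf_plan)
            d = DoseVolumeHistogram.uniform(d_phys)
            assert effective_dose(d, cf_plan, params) == pytest.approx(30.0, rel=1e-9)

    def test_n_of_one_is_mean_eqd(self, cf_plan):
        params = TissueParameters(organ="x", alpha_beta=4.0, n_volume=1.0)
        d = dvh_with_eqds([0.0, 40.0], [0.5, 0.5], cf_plan)
        assert effective_dose(d, cf_plan, params) == pytest.approx(20.0, rel=1e-9)

    def test_brute_force_generalized_mean(self, cf_plan):
        params = TissueParameters(organ="x", alpha_beta=4.0, n_volume=0.5)
        d = dvh_with_eqds([20.0, 40.0], [0.5, 0.5], cf_plan)
        expected = (0.5 * 20.0**2 + 0.5 * 40.0**2) ** 0.5
        result = effective_dose(d, cf_plan, params)
        assert result == pytest.approx(expected, rel=1e-9)
        assert result == pytest.approx(31.62, abs=0.01)

    def test_ntcp_half_at_d50(self, cf_plan, tissue):
        d = DoseVolumeHistogram.uniform(physical_dose_for_eqd(37.6, cf_plan))
        assert ntcp_lkb(d, cf_plan, tissue["lung"]) == pytest.approx(0.5, abs=1e-9)

    def test_lung_normal_cdf_oracle(self, cf_plan, tissue):
        d = DoseVolumeHistogram.uniform(physical_dose_for_eqd(20.0, cf_plan))
        t = (20.0 - 37.6) / (0.35 * 37.6)
        assert ntcp_lkb(d, cf_plan, tissue["lung"]) == pytest.approx(float(ndtr(t)), rel=1e-9)
        assert ntcp_lkb(d, cf_plan, tissue["lung"]) == pytest.approx(0.0906, abs=2e-4)

    def test_heart_zero_dose_deep_tail(self, cf_plan, tissue):
        d = DoseVolumeHistogram.uniform(0.0)
        assert ntcp_lkb(d, cf_plan, tissue["heart"]) < 1e-12

    def test_strictly_increasing_in_dose(self, cf_plan, tissue):
        values = [
            ntcp_lkb(DoseVolumeHistogram.uniform(d), cf_plan, tissue["lung"])
            for d in (5.0, 15.0, 25.0, 35.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(0 < v < 1 for v in values)


class TestStructuralInvariances:
    """Endpoints depend only on the (dose, volume) distribution."""

    def test_bin_merge_and_permutation_invariance(self, cf_plan, tissue):
        # same mass at EQD 50 split across two adjacent delta bins vs one
        split = dvh_with_eqds([49.999, 50.001], [0.4, 0.6], cf_plan)
        merged = dvh_with_eqds([50.0], [1.0], cf_plan)
        for fn, key in ((tcp_poisson_lq, "breast_ptv"), (eud, "breast_ptv"), (effective_dose, "lung"), (ntcp_lkb, "lung")):
            assert fn(split, cf_plan, tissue[key]) == pytest.approx(
                fn(merged, cf_plan, tissue[key]), rel=1e-4
            )

    def test_binned_converges_to_voxel_list(self, cf_plan, tissue):
        # coarse 1.0 Gy binning vs fine 0.01 Gy binning of the same voxel doses
        rng = np.random.default_rng(42)
        doses = np.clip(rng.normal(51.8, 1.0, size=20000), 0, None)
        fine = DoseVolumeHistogram.from_doses(doses, bin_width=0.01)
        coarse = DoseVolumeHistogram.from_doses(doses, bin_width=1.0)
        for fn, key in ((eud, "breast_ptv"), (tcp_poisson_lq, "breast_ptv"), (ntcp_lkb, "lung")):
            f, c = fn(fine, cf_plan, tissue[key]), fn(coarse, cf_plan, tissue[key])
            assert c == pytest.approx(f, rel=1e-3)

    def test_scaling_dose_up_increases_all_endpoints(self, cf_plan, tissue, random_dvh):
        base = random_dvh(n_bins=10, seed=9, bin_width=0.5, start=30.0)
        hot = DoseVolumeHistogram(
            "s", base.bin_edges * 1.1, base.volume_fraction, base.absolute_volume
        )
        assert eud(hot, cf_plan, tissue["breast_ptv"]) > eud(base, cf_plan, tissue["breast_ptv"])
        assert tcp_poisson_lq(hot, cf_plan, tissue["breast_ptv"]) > tcp_poisson_lq(
            base, cf_plan, tissue["breast_ptv"]
        )
        assert effective_dose(hot, cf_plan, tissue["lung"]) > effective_dose(
            base, cf_plan, tissue["lung"]
        )
        assert ntcp_lkb(hot, cf_plan, tissue["lung"]) > ntcp_lkb(base, cf_plan, tissue["lung"])


class TestParameterRegistry:
    def test_defaults_cover_all_roles(self, tissue):
        assert set(tissue) == {"breast_ptv", "heart", "lung"}
        assert tissue["breast_ptv"].a_exponent == -7.2
        assert tissue["breast_ptv"].gamma == 1.3
        assert tissue["breast_ptv"].d50 == 30.89
        assert tissue["heart"].d50 == 48.0 and tissue["heart"].m_slope == 0.1
        assert tissue["lung"].n_volume == 0.87

    def test_structure_role_mapping(self, tissue):
        assert tissue_for_structure("ipsilateral_lung", tissue) is tissue["lung"]
        assert tissue_for_structure("PTV", tissue) is tissue["breast_ptv"]
        with pytest.raises(ParameterError):
            tissue_for_structure("spinal_cord", tissue)

    def test_yaml_override(self, tmp_path, tissue):
        from planeval import load_tissue_parameters

        f = tmp_path / "override.yaml"
        f.write_text("lung:\n  alpha_beta: 3.0\n  d50: 30.0\n  m: 0.4\n  n: 0.9\n")
        reg = load_tissue_parameters(f)
        assert reg["lung"].d50 == 30.0 and reg["lung"].alpha_beta == 3.0
        assert reg["heart"].d50 == tissue["heart"].d50  # untouched default

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            TissueParameters(organ="x", alpha_beta=-1.0)
        with pytest.raises(ParameterError):
            TissueParameters(organ="x", alpha_beta=4.0, n_volume=1.5)
        with pytest.raises(ParameterError):
            TissueParameters(organ="x", alpha_beta=4.0, m_slope=0.0)
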