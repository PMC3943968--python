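"""Generator determinism, class invariants and the closed-form forward model."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_catalog
from csfpre.synthetic_data import (
    ALBUMIN_SENTINEL,
    SimulationSpec,
    generate_catalog,
    multiplicative_noise,
    simulate_blood_spike,
    simulate_centrifugation_pair,
    simulate_plasma_csf_pairs,
    simulate_rcg_series,
    simulate_spike_experiment,
)


class TestCatalog:
    def test_same_seed_gives_identical_catalogs(self):
        spec = SimulationSpec(seed=42)
        a, b = generate_catalog(spec), generate_catalog(spec)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_cns_only_catalog_is_flat_and_cell_free(self):
        spec = SimulationSpec(seed=1, n_per_class={"cns": 30})
        cat = generate_catalog(spec)
        t = cat.table.drop(index=ALBUMIN_SENTINEL)
        assert (t["origin"] == "cns").all()
        assert (t["gradient_amp"] == 1.0).all()
        assert (t["cell_assoc_frac"] == 0.0).all()

    def test_albumin_sentinel_always_present_with_ratio_177(self):
        cat = generate_catalog(SimulationSpec(seed=3))
        assert cat.table.at[ALBUMIN_SENTINEL, "r_volume"] == 177.0

    def test_blood_cellular_proteins_are_cell_associated(self):
        cat = generate_catalog(SimulationSpec(seed=5))
        cellular = cat.table[cat.table["origin"] == "blood_cellular"]
        assert (cellular["cell_assoc_frac"] >= 0.9).all()
        assert (cellular["payload_ratio"] > 0).all()

    def test_zero_proteins_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            generate_catalog(SimulationSpec(seed=1, n_per_class={"cns": 0}))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(noise_cv=-0.1),
            dict(spike_fractions=(1.5,)),
            dict(centrifugation_removal=2.0),
            dict(n_rcg_points=2),
            dict(n_patients=1),
            dict(n_per_class={"martian": 5}),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSpec(seed=1, **kwargs)


class TestBloodSpike:
    def test_zero_fraction_reproduces_csf_concentration(self):
        cat = make_catalog({"A": {"c_csf": 5.0, "r_volume": 100.0, "origin": "plasma_liver"}})
        m = simulate_blood_spike(cat, 0.0, noise_cv=0.0, seed=1)
        assert m.values.at["A", "spike_0"] == pytest.approx(5.0)

    def test_albumin_like_fold_change_at_two_percent(self):
        # fc = (1 - f) + f * r = 0.98 + 0.02 * 177 = 4.52, the typical
        # four-fold increase of liver-secreted proteins at a 2% spike
        cat = make_catalog({"A": {"c_csf": 2.0, "r_volume": 177.0, "origin": "plasma_liver"}})
        m = simulate_blood_spike(cat, 0.02, noise_cv=0.0, seed=1)
        fc = m.values.at["A", "spike_0.02"] / m.values.at["A", "reference"]
        assert fc == pytest.approx(4.52, abs=1e-12)

    def test_pure_cns_protein_is_only_diluted(self):
        cat = make_catalog({"A": {"c_csf": 3.0, "r_volume": 0.0}})
        m = simulate_blood_spike(cat, 0.005, noise_cv=0.0, seed=1)
        fc = m.values.at["A", "spike_0.005"] / m.values.at["A", "reference"]
        assert fc == pytest.approx(0.995, abs=1e-12)

    def test_centrifugation_removes_cellular_payload_only(self):
        cat = make_catalog(
            {"H": {"origin": "blood_cellular", "c_csf": 1.0, "r_volume": 0.0,
                   "cell_assoc_frac": 1.0, "payload_ratio": 1000.0}}
        )
        spec = SimulationSpec(seed=1, noise_cv=0.0, centrifugation_removal=0.95)
        pair = simulate_centrifugation_pair(cat, spec, fraction=0.01)
        spun = pair.values.at["H", "spike_0.01"]
        unspun = pair.values.at["H", "spike_0.01_nc"]
        # kept payload: 5% when spun vs 100% when not
        assert unspun / spun == pytest.approx(
            (0.99 + 0.01 * 1000) / (0.99 + 0.01 * 1000 * 0.05), rel=1e-12
        )

    def test_negative_fraction_rejected(self, noise_free_catalog):
        with pytest.raises(ValueError):
            simulate_blood_spike(noise_free_catalog, -0.01, seed=1)

    def test_same_seed_bit_reproducible(self, noise_free_catalog):
        spec = SimulationSpec(seed=9)
        a = simulate_spike_experiment(noise_free_catalog, spec)
        b = simulate_spike_experiment(noise_free_catalog, spec)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestRcgSeries:
    def test_flat_protein_identical_at_all_points(self):
        cat = make_catalog({"A": {"c_csf": 4.0, "gradient_amp": 1.0}})
        spec = SimulationSpec(seed=1, noise_cv=0.0)
        m = simulate_rcg_series(cat, spec)
        point_cols = [c for c in m.sample_ids if c != "reference"]
        assert np.allclose(m.values.loc["A", point_cols], 4.0)

    def test_gradient_protein_end_to_end_ratio_and_reference_mean(self):
        cat = make_catalog(
            {"A": {"origin": "plasma_liver", "c_csf": 2.0, "r_volume": 177.0,
                   "gradient_amp": 1.6}}
        )
        spec = SimulationSpec(seed=1, noise_cv=0.0)
        m = simulate_rcg_series(cat, spec)
        v = m.values.loc["A"]
        assert v["rcg1_rep1"] / v["rcg7_rep1"] == pytest.approx(1.6, abs=1e-12)
        points = [v["rcg1_rep1"], v["rcg2"], v["rcg3"], v["rcg4"], v["rcg5"], v["rcg6"],
                  v["rcg7_rep1"]]
        assert v["reference"] == pytest.approx(np.mean(points), abs=1e-12)
        # linear by construction: second differences vanish
        assert np.allclose(np.diff(points, n=2), 0.0, atol=1e-12)

    def test_end_points_have_duplicate_channels(self, noise_free_catalog, noise_free_spec):
        m = simulate_rcg_series(noise_free_catalog, noise_free_spec)
        points = [m.meta(s).rcg_point for s in m.sample_ids if m.meta(s).role == "rcg_point"]
        assert points.count(1) == 2 and points.count(7) == 2 and points.count(4) == 1

    def test_hemoglobin_point1_spike_only_boosts_cellular_point1(self):
        cat = make_catalog(
            {
                "H": {"origin": "blood_cellular", "c_csf": 1.0, "cell_assoc_frac": 1.0,
                      "payload_ratio": 1000.0, "gradient_amp": 1.6},
                "A": {"c_csf": 1.0},
            }
        )
        spec = SimulationSpec(seed=1, noise_cv=0.0, hemoglobin_point1_spike=True,
                              hb_point1_factor=10.0)
        m = simulate_rcg_series(cat, spec)
        base = simulate_rcg_series(cat, SimulationSpec(seed=1, noise_cv=0.0))
        assert m.values.at["H", "rcg1_rep1"] == pytest.approx(
            10.0 * base.values.at["H", "rcg1_rep1"]
        )
        assert m.values.at["A", "rcg1_rep1"] == base.values.at["A", "rcg1_rep1"]
        assert m.values.at["H", "rcg2"] == base.values.at["H", "rcg2"]


class TestPlasmaCsfPairs:
    def test_zero_ratio_protein_absent_from_plasma(self):
        cat = make_catalog({"A": {"c_csf": 2.0, "r_volume": 0.0},
                            "B": {"c_csf": 1.0, "r_volume": 10.0, "origin": "mixed"}})
        spec = SimulationSpec(seed=1, noise_cv=0.0, patient_sigma=0.0)
        exp = simulate_plasma_csf_pairs(cat, spec)
        for basis in (exp.equal_volume, exp.equal_protein):
            assert basis.values.at["A", "P1_plasma"] == 0.0

    def test_equal_protein_rescaling_algebra(self):
        # a protein whose r_volume equals the total-protein concentration
        # ratio has an equal-protein-basis ratio of exactly 1
        cat = make_catalog(
            {
                "A": {"c_csf": 2.0, "r_volume": 50.0, "origin": "plasma_liver"},
                "B": {"c_csf": 6.0, "r_volume": 50.0, "origin": "plasma_liver"},
            }
        )
        spec = SimulationSpec(seed=1, noise_cv=0.0, patient_sigma=0.0)
        exp = simulate_plasma_csf_pairs(cat, spec)
        ep = exp.equal_protein.values
        assert ep.at["A", "P1_plasma"] / ep.at["A", "P1_CSF"] == pytest.approx(1.0, abs=1e-12)
        # and in general equal-protein = equal-volume x (total CSF / total plasma)
        ev = exp.equal_volume.values
        tot = exp.total_protein
        lhs = ep.at["B", "P2_plasma"] / ep.at["B", "P2_CSF"]
        rhs = (ev.at["B", "P2_plasma"] / ev.at["B", "P2_CSF"]) * tot["P2_CSF"] / tot["P2_plasma"]
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_same_seed_identical_matrices(self, noise_free_catalog):
        spec = SimulationSpec(seed=11)
        a = simulate_plasma_csf_pairs(noise_free_catalog, spec)
        b = simulate_plasma_csf_pairs(noise_free_catalog, spec)
        pd.testing.assert_frame_equal(a.equal_volume.values, b.equal_volume.values)
        pd.testing.assert_frame_equal(a.equal_protein.values, b.equal_protein.values)


class TestNoiseModel:
    def test_cv_calibration_at_nominal_twenty_percent(self):
        rng = np.random.default_rng(123)
        factors = multiplicative_noise(rng, (1000, 30), 0.20)
        cv = factors.std(axis=1, ddof=1) / factors.mean(axis=1)
        assert 0.18 <= cv.mean() <= 0.22

    def test_noise_factors_have_unit_mean(self):
        rng = np.random.default_rng(1)
        factors = multiplicative_noise(rng, (200_000,), 0.20)
        assert factors.mean() == pytest.approx(1.0, abs=0.005)

    def test_zero_cv_is_exactly_noise_free(self):
        rng = np.random.default_rng(1)
        assert (multiplicative_noise(rng, (5, 5), 0.0) == 1.0).all()
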