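"""Generator contracts: closed-form expectations, determinism, ground truth."""

import numpy as np
import pytest

from ptcrescue.presets import activity_spec, blot_spec, flow_model, scene_spec
from ptcrescue.synthetic_data import (
    ActivitySample,
    AssaySimSpec,
    BlotLane,
    BlotSimSpec,
    ImageSceneSpec,
    ReporterCellModel,
    make_synthetic_cds,
    simulate_activity_plate,
    simulate_blot,
    simulate_flow_sample,
    simulate_image_scene,
)


class TestFlowGenerator:
    def test_fusion_control_identity(self, clean_model):
        """theta=1, no noise/autofluorescence, equal gains: GFP == RFP."""
        events = simulate_flow_sample(clean_model(1.0), 2000, seed=1)
        transfected = events.data[events.data["RFP"] > 0]
        assert len(transfected) > 0
        np.testing.assert_array_equal(
            transfected["GFP"].to_numpy(), transfected["RFP"].to_numpy()
        )

    def test_theta_zero_gives_zero_gfp(self, clean_model):
        events = simulate_flow_sample(clean_model(0.0), 2000, seed=2)
        assert (events.data["GFP"] == 0).all()

    def test_population_ratio_matches_theta(self, clean_model):
        """Closed form: E[GFP]/E[RFP] over transfected events equals theta."""
        theta = 0.002
        events = simulate_flow_sample(clean_model(theta, noise_cv=0.1), 200_000, seed=3)
        t = events.data[events.data["RFP"] > 0]
        ratio = t["GFP"].mean() / t["RFP"].mean()
        # delta-method standard error of the ratio of means
        n = len(t)
        se = ratio * np.sqrt(
            t["GFP"].var() / (n * t["GFP"].mean() ** 2)
            + t["RFP"].var() / (n * t["RFP"].mean() ** 2)
        )
        assert abs(ratio - theta) < 3 * se

    def test_rfp_moment_matches_lognormal_mean(self, clean_model):
        """Mean transfected RFP ~= gain * exp(mu + sigma^2/2) within 3 s.e."""
        model = clean_model(0.0)
        expected = model.rfp_gain * np.exp(
            model.expression_log_mean + model.expression_log_sd**2 / 2
        )
        devs = []
        for seed in range(10):
            ev = simulate_flow_sample(model, 20_000, seed=seed)
            t = ev.data[ev.data["RFP"] > 0]["RFP"]
            se = t.std() / np.sqrt(len(t))
            devs.append(abs(t.mean() - expected) / se)
        assert np.mean(devs) < 3.0

    def test_debris_outside_scatter_gate(self):
        model = ReporterCellModel(theta=0.5, debris_fraction=1.0)
        ev = simulate_flow_sample(model, 5000, seed=4)
        inside = (
            (ev.data["FSC"] >= 23_000) & (ev.data["FSC"] <= 75_000)
            & (ev.data["SSC"] >= 12_500) & (ev.data["SSC"] <= 67_500)
        )
        assert inside.mean() < 0.05

    def test_seed_determinism(self):
        model = flow_model("q82x_untreated")
        a = simulate_flow_sample(model, 5000, seed=9)
        b = simulate_flow_sample(model, 5000, seed=9)
        assert a.data.equals(b.data)

    def test_invalid_model_names_field(self):
        with pytest.raises(ValueError, match="transfected_fraction"):
            ReporterCellModel(theta=0.5, transfected_fraction=1.5)
        with pytest.raises(ValueError, match="theta"):
            ReporterCellModel(theta=-0.1)

    def test_n_events_validated(self):
        with pytest.raises(ValueError):
            simulate_flow_sample(flow_model("control_100pct"), 0, seed=1)


class TestImageSceneGenerator:
    def test_all_within_when_fraction_one(self):
        spec = scene_spec("wild_type", seed=11, fraction_within_02um=1.0,
                          photon_noise_scale=0.0, n_fuca1=40)
        _, truth = simulate_image_scene(spec)
        assert (truth["fuca1"]["edge_to_edge_um"] <= 0.2).all()

    def test_no_puncta_valid_scene(self):
        spec = scene_spec("wild_type", seed=12, n_fuca1=0)
        img, truth = simulate_image_scene(spec)
        assert truth["fuca1"].empty
        assert img.shape == (2, 512, 512)

    def test_realized_fraction_binomial(self):
        spec = scene_spec("wild_type", seed=13, n_fuca1=100)
        _, truth = simulate_image_scene(spec)
        frac = (truth["fuca1"]["edge_to_edge_um"] <= 0.2).mean()
        # binomial 3-sigma band around 0.6 at n=100
        assert abs(frac - 0.6) <= 3 * np.sqrt(0.6 * 0.4 / 100)

    def test_ground_truth_self_consistent(self):
        """Recomputing edge distances from centroids/radii reproduces truth."""
        spec = scene_spec("wild_type", seed=14)
        _, truth = simulate_image_scene(spec)
        lam = truth["lamp1"]
        for _, row in truth["fuca1"].iterrows():
            d = np.hypot(lam["y_um"] - row["y_um"], lam["x_um"] - row["x_um"])
            edges = np.maximum(0.0, d - lam["radius_um"] - row["radius_um"])
            k = int(np.argmin(edges))
            assert lam["label"].iloc[k] == row["nearest_lamp1"]
            assert edges.iloc[k] == pytest.approx(row["edge_to_edge_um"], abs=1e-12)
            assert d.iloc[k] == pytest.approx(row["center_to_center_um"], abs=1e-12)

    def test_scene_determinism(self):
        spec = scene_spec("wild_type", seed=15)
        img1, t1 = simulate_image_scene(spec)
        img2, t2 = simulate_image_scene(spec)
        np.testing.assert_array_equal(img1, img2)
        assert t1["fuca1"].equals(t2["fuca1"])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="fraction_within_02um"):
            ImageSceneSpec(fraction_within_02um=1.5)
        with pytest.raises(ValueError, match="lamp1_diameter_um"):
            ImageSceneSpec(lamp1_diameter_um=(0.4, 0.8))
        with pytest.raises(ValueError, match="beyond_gap_um"):
            ImageSceneSpec(beyond_gap_um=(0.1, 0.5))


class TestActivityPlateGenerator:
    def test_standard_reading_arithmetic(self):
        spec = AssaySimSpec(curve_slope=100.0, curve_intercept=50.0,
                            standard_points=(0.0, 7.5))
        plate = simulate_activity_plate(spec, seed=0)
        top = plate[(plate["role"] == "standard") & (plate["nmol_4mu"] == 7.5)]
        assert top["reading"].iloc[0] == pytest.approx(800.0)

    def test_zero_activity_reads_blank(self):
        spec = AssaySimSpec(samples=(ActivitySample("null", 0.0),))
        plate = simulate_activity_plate(spec, seed=0)
        s = plate[plate["role"] == "sample"]
        assert s["reading"].iloc[0] == pytest.approx(spec.curve_intercept)

    def test_standards_must_include_blank(self):
        with pytest.raises(ValueError, match="standard_points"):
            AssaySimSpec(standard_points=(1.0, 2.0))

    def test_noise_reproducible(self):
        spec = activity_spec(["wt_untreated"], read_noise_sd=5.0)
        a = simulate_activity_plate(spec, seed=1)
        b = simulate_activity_plate(spec, seed=1)
        assert a.equals(b)


class TestBlotGenerator:
    def test_load_proportionality(self):
        spec = BlotSimSpec(
            lanes=(
                BlotLane("a", "x", 25.0, {"T": 1.0}),
                BlotLane("b", "y", 0.25, {"T": 1.0}),
            )
        )
        t = simulate_blot(spec, seed=0)
        ia = t[(t["lane"] == "a") & (t["target"] == "T")]["intensity"].iloc[0]
        ib = t[(t["lane"] == "b") & (t["target"] == "T")]["intensity"].iloc[0]
        assert ia / ib == pytest.approx(100.0)

    def test_zero_abundance_zero_band(self):
        spec = BlotSimSpec(lanes=(BlotLane("a", "x", 25.0, {"T": 0.0}),))
        t = simulate_blot(spec, seed=0)
        assert t[t["target"] == "T"]["intensity"].iloc[0] == 0.0

    def test_loading_control_present_per_lane(self):
        t = simulate_blot(blot_spec("erf3a_cc885_5nm"), seed=0)
        per_lane = t[t["target"] == "GAPDH"].groupby("lane").size()
        assert (per_lane == 1).all()

    def test_control_among_abundances_rejected(self):
        with pytest.raises(ValueError, match="exactly one control"):
            BlotSimSpec(lanes=(BlotLane("a", "x", 25.0, {"GAPDH": 1.0}),))


def test_synthetic_cds_structure():
    seq = make_synthetic_cds(seed=0)
    assert seq.n_codons == 467  # 466 residues + stop
    assert seq.codon(82) == "CAG"
    assert seq.codon(188) == "TGG"
    assert seq.codon(427) == "CAA"
    seq.check_no_internal_stop()
    assert make_synthetic_cds(seed=0).cds == seq.cds
    assert make_synthetic_cds(seed=1).cds != seq.cds
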