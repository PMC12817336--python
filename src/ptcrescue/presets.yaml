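# Preset catalog: named study conditions with their ground-truth parameters.
# Flow presets share one base measurement model; `theta` is the true
# readthrough fraction (theta = 1 encodes the stop-free fusion control).
version: 1

flow_base:
  transfected_fraction: 0.35
  expression_log_mean: 10.8
  expression_log_sd: 0.5
  rfp_gain: 1.0
  gfp_gain: 1.0
  autofluor_rfp_mean: 45.0
  autofluor_gfp_mean: 0.5
  autofluor_sd: 0.8
  fsc_mean: 49000.0
  fsc_sd: 8000.0
  ssc_mean: 40000.0
  ssc_sd: 9000.0
  debris_fraction: 0.08
  noise_cv: 0.15

flow:
  control_100pct:
    theta: 1.0
    description: "Stop-free RFP-GFP fusion control; defines 100% readthrough."
  q82x_untreated:
    theta: 0.002
    description: "p.Q82X (UAG) reporter, untreated; basal readthrough 0.2%."
  w188x_untreated:
    theta: 0.0002
    description: "p.W188X (UGA) reporter, untreated; basal readthrough 0.02%."
  q427x_untreated:
    theta: 0.0034
    description: "p.Q427X (UAA) reporter, untreated; basal readthrough 0.34%."
  g418_500:
    theta: 0.005
    description: "500 ng/ul G418 alone (p.Q82X / p.W188X); readthrough 0.5%."
  g418_100_cc885_1nm:
    theta: 0.01
    description: "100 ng/ul G418 + 1 nM CC-885; readthrough induced to 1%."
  g418_100_cc885_5nm:
    theta: 0.012
    description: "100 ng/ul G418 + 5 nM CC-885; readthrough induced above 1%."

proximity:
  wild_type:
    image_shape: [512, 512]
    pixel_size_um: 0.1
    n_lamp1: 60
    lamp1_diameter_um: [0.2, 0.3]
    n_fuca1: 100
    fuca1_diameter_um: 0.2
    fraction_within_02um: 0.6
    within_radius_um: 0.2
    beyond_gap_um: [0.44, 0.54]
    psf_sigma_px: 0.8
    background_level: 20.0
    background_gradient: 10.0
    photon_noise_scale: 8.0
    lamp1_amplitude: 180.0
    fuca1_amplitude: 200.0
    description: >-
      Wild-type lysosomal geometry: luminal enzyme puncta against membrane-
      marker discs under 0.7 um diameter; 60% of puncta within 0.2 um
      edge-to-edge, mean center-to-center distance ~0.35 um.

# Specific activities in mU/mg (1 mU = 1 nmol 4-MU per minute).
activity:
  wt_untreated:
    true_activity_mU_per_mg: 100.0
    protein_mg: 0.02
    dilution_factor: 100.0
    incubation_min: 30.0
    description: "Wild-type enzyme, untreated lysate (1:100 dilution for linearity)."
  q82x_g418_max:
    true_activity_mU_per_mg: 1.46
    protein_mg: 0.02
    dilution_factor: 1.0
    incubation_min: 30.0
    description: "p.Q82X, maximal recovery under G418 alone."
  w188x_g418_max:
    true_activity_mU_per_mg: 0.88
    protein_mg: 0.02
    dilution_factor: 1.0
    incubation_min: 30.0
    description: "p.W188X, maximal recovery under G418 alone."
  q82x_g418_cc885_5nm:
    true_activity_mU_per_mg: 3.65
    protein_mg: 0.02
    dilution_factor: 1.0
    incubation_min: 30.0
    description: "p.Q82X, 100 ng/ul G418 + 5 nM CC-885 (3.65% of untreated WT)."
  w188x_g418_cc885_5nm:
    true_activity_mU_per_mg: 1.19
    protein_mg: 0.02
    dilution_factor: 1.0
    incubation_min: 30.0
    description: "p.W188X, 100 ng/ul G418 + 5 nM CC-885 (1.19% of untreated WT)."

activity_curve:
  curve_slope: 100.0
  curve_intercept: 50.0
  standard_points: [0.0, 0.25, 0.5, 1.0, 2.5, 5.0, 7.5]

blot:
  erf3a_cc885_5nm:
    description: "Release-factor degradation: eRF3a halved at 5 nM CC-885."
    loading_control_target: GAPDH
    lanes:
      - lane: L1
        condition: untreated
        load_ug: 25.0
        abundances: {eRF3a: 1.0}
      - lane: L2
        condition: cc885_5nm
        load_ug: 25.0
        abundances: {eRF3a: 0.5}
  efficacy_dual_treatment:
    description: >-
      Full-length recovery: variant band vs wild type loaded at 1%;
      dual treatment recovers ~3% of wild-type full-length protein.
    loading_control_target: GAPDH
    wt_reference_lane: WT
    wt_reference_load_fraction: 0.01
    lanes:
      - lane: WT
        condition: wt_untreated
        load_ug: 25.0
        abundances: {FUCA1_full_length: 1.0}
      - lane: V1
        condition: q82x_dual
        load_ug: 25.0
        abundances: {FUCA1_full_length: 0.03}
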