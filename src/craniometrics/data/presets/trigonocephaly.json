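{
 "name": "trigonocephaly",
 "height_cm": 13.2,
 "ap_semi_axis_cm": 9.687599764877763,
 "ml_semi_axis_cm": 7.5,
 "ap_taper": 0.6,
 "ml_taper": 0.6,
 "anterior_scale_r": 0.75261076730623,
 "anterior_scale_l": 0.75261076730623,
 "exponent": 2.0,
 "frontal_angle_deg": 130.0,
 "frontoparietal_angle_deg": 130.0,
 "frontal_asym": 0.0,
 "frontoparietal_asym": 0.0,
 "nasion_y_frac": 0.9,
 "nasion_z_cm": 1.0,
 "orbit_ray_cm": 4.8,
 "parietal_ray_cm": 8.0,
 "noise_amplitude_cm": 0.0,
 "contour_points": 128,
 "rings_per_layer": 3,
 "apex_rings_per_layer": 7
}
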