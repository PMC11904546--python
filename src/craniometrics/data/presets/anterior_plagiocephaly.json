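{
 "name": "anterior_plagiocephaly",
 "height_cm": 13.2,
 "ap_semi_axis_cm": 7.9177532731744895,
 "ml_semi_axis_cm": 7.5,
 "ap_taper": 0.6,
 "ml_taper": 0.6,
 "anterior_scale_r": 1.1510512579847518,
 "anterior_scale_l": 0.9208410063878015,
 "exponent": 2.0,
 "frontal_angle_deg": 140.0,
 "frontoparietal_angle_deg": 134.0,
 "frontal_asym": 0.02,
 "frontoparietal_asym": 0.04,
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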