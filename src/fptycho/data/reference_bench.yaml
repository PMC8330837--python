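wavelength_um: 0.532
led_rows: 15
led_cols: 15
led_pitch_mm: 4.0
led_distance_mm: 90.0
na_obj: 0.1
magnification: 2.0
camera_pixel_um: 3.45
lowres_size: 32
upsample_factor: 4
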