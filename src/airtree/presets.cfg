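# Named parameter presets for the airway pipeline.
# Values are plain key = value pairs; lists are comma-separated.

[lung-airways]
# Patient-scale thoracic CT, ~0.5 mm voxels.
air_threshold_hu = -500
scales_mm = 1.5, 2, 3, 4.5, 6, 9
contrast_hu = 100
probability_threshold = 0.15
prune_length_mm = 4.0
dilation_radius_mm = 1.0
hu_ceiling = -500
gradient_factor = 1.0
intensity_margin_hu = 75
connectivity = 26
lower_hu = -990
upper_hu = -120

[lung-airways-phantom]
# Synthetic branching-airway phantoms (capsule tubes, clean walls).
air_threshold_hu = -500
scales_mm = 1.5, 2, 3, 4.5, 6, 9
contrast_hu = 100
probability_threshold = 0.15
prune_length_mm = 4.0
dilation_radius_mm = 1.0
hu_ceiling = -500
gradient_factor = 1.0
intensity_margin_hu = 75
connectivity = 26
lower_hu = -990
upper_hu = -120
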