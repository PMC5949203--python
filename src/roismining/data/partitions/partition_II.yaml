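# Region-of-interest partition II: ten bilaterally symmetric functional
# regions (left/right prefrontal, premotor, auditory, visual, somatosensory
# cortex projections), 68 of 128 channels on a 128-channel geodesic net.
#
# As for partition I, per-electrode assignments follow standard HydroCel
# GSN-128 geography constrained to the published 68-channel total; edit as
# data if your montage differs.
name: partition_II
regions:
  - label: PFC_L  # Left Prefrontal Cortex
    channels: [E22, E23, E26, E27, E32, E33, E38]
  - label: PFC_R  # Right Prefrontal Cortex
    channels: [E1, E2, E8, E9, E14, E121, E122]
  - label: PMC_L  # Left Premotor Cortex
    channels: [E13, E19, E20, E24, E28, E29, E34]
  - label: PMC_R  # Right Premotor Cortex
    channels: [E3, E4, E111, E116, E117, E118, E123]
  - label: AC_L   # Left Auditory Cortex
    channels: [E39, E40, E41, E45, E46, E50, E51]
  - label: AC_R   # Right Auditory Cortex
    channels: [E98, E101, E102, E103, E108, E109, E115]
  - label: VC_L   # Left Visual Cortex
    channels: [E64, E65, E66, E69, E70, E71, E74]
  - label: VC_R   # Right Visual Cortex
    channels: [E76, E82, E83, E84, E89, E90, E95]
  - label: SC_L   # Left Somatosensory Cortex
    channels: [E30, E31, E36, E37, E42, E53]
  - label: SC_R   # Right Somatosensory Cortex
    channels: [E80, E87, E93, E104, E105, E110]
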