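# Region-of-interest partition I: ten scalp regions of 7 electrode sites each
# (70 of 128 channels) on a 128-channel geodesic sensor net.
#
# The published electrode-to-region assignment exists only as a figure; the
# assignments below follow standard HydroCel GSN-128 scalp geography and
# honour the published cardinalities (10 regions x 7 channels).  This file is
# data, not code: edit the channel lists to match your montage if needed.
name: partition_I
regions:
  - label: CF    # Centrofrontal
    channels: [E4, E5, E10, E11, E12, E16, E18]
  - label: LAL   # Left Anterior Lateral
    channels: [E23, E26, E27, E33, E34, E39, E40]
  - label: RAL   # Right Anterior Lateral
    channels: [E2, E109, E115, E116, E121, E122, E123]
  - label: LAM   # Left Anterior Medial
    channels: [E13, E19, E20, E24, E28, E29, E35]
  - label: RAM   # Right Anterior Medial
    channels: [E3, E103, E104, E110, E111, E117, E118]
  - label: LPM   # Left Posterior Medial
    channels: [E37, E42, E47, E52, E53, E54, E61]
  - label: RPM   # Right Posterior Medial
    channels: [E78, E79, E85, E86, E87, E92, E93]
  - label: LOT   # Left Occipitotemporal
    channels: [E50, E51, E57, E58, E59, E64, E65]
  - label: ROT   # Right Occipitotemporal
    channels: [E90, E91, E95, E96, E97, E100, E101]
  - label: CO    # Centrooccipital
    channels: [E62, E67, E71, E72, E75, E76, E77]
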