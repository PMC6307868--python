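# Example run configuration for `neurorg motility --config run.yaml`.
# Every key is optional; omitted keys take the defaults shown here.
# Unknown keys are rejected by name.

imaging:
  pixel_size: 0.08        # um per pixel
  frame_interval: 5.0     # seconds
  n_frames: 97            # 96 intervals = 480 s
  frame_shape: [512, 512]

frangi:
  scales: [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]   # px
  beta: 0.5
  gamma: null             # null -> half the max Hessian norm per scale

hysteresis:
  noise_mult: 8.0         # low threshold = 8 x median nonzero ridge strength

soma:
  dog_scales: [10.0, 15.0, 20.0, 25.0, 30.0, 40.0]
  open_radius_px: 12
  soma_margin_px: 3
  downsample: 2

detection:
  sigma_po: 1.0           # px
  sigma_mito: 2.0
  sigma_fixed: 0.0        # fixed-cell images: raw Otsu
  min_size: 4             # px

tracking:
  max_link_dist: 1.0      # um per frame

motility:
  displacement_floor: 0.1  # um; steps below this count as zero distance
  min_track_fraction: 0.8  # cohort filter: track must span 80% of the session

distribution:
  proximal_length: 30.0   # um of neurite measured from the soma
  contact_dilation_px: 1  # 8-adjacency for PO-mitochondria contact

input_dir: fixtures/neuron_00
output_dir: out/neuron_00
seed: 0
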