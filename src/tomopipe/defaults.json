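{
  "general": {
    "pixel_size": 1.0,
    "seed": 0,
    "n_items": 1,
    "gold_bead_diameter_nm": [5],
    "tilt_convention": "y-axis"
  },
  "modules": {
    "simulate": {
      "volume_xy": 128,
      "thickness": 64,
      "phantom": "torus",
      "phantom_box": 24,
      "n_particles": 10,
      "min_dist": 28.0,
      "border": 16.0,
      "tilt_start": -45.0,
      "tilt_stop": 45.0,
      "tilt_step": 3.0,
      "dose_per_tilt": 3.0,
      "defocus": 3.0,
      "snr": 0.5
    },
    "estimate_ctf": {
      "search_min": 1.0,
      "search_max": 6.0,
      "step": 0.05
    },
    "reconstruct": {
      "binning": 1,
      "thickness": 64,
      "filter": "ramp*hamming",
      "nad_iterations": 0
    },
    "template_match": {
      "template_phantom": "torus",
      "template_box": 24,
      "lowpass": 1e30,
      "cone_sampling": 20.0,
      "cone_range": 360.0,
      "inplane_sampling": 20.0,
      "inplane_range": 360.0,
      "symmetry": "C1",
      "chunk_size": 0,
      "taper": 0,
      "tilt_start": -45.0,
      "tilt_stop": 45.0,
      "tilt_step": 3.0,
      "threshold_sigma": 5.0,
      "max_particles": 100,
      "exclusion_radius": 12.0,
      "island_max_size": 1e30
    },
    "cleanup": {
      "stages": ["cc_maps"],
      "dry_run": false
    }
  }
}
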