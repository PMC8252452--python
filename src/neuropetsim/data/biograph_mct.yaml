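# Siemens Biograph mCT (LSO). Reconstruction grid/voxel follow the clinical
# brain protocol; ring geometry, energy resolution and window are implementer
# defaults from vendor literature and may be overridden. TOF and resolution
# recovery are not modeled.
name: biograph_mct
ring_radius_mm: 421.5
n_rings: 55
n_crystals_per_ring: 624
crystal_axial_pitch_mm: 4.06
energy_resolution_fwhm_fraction: 0.12
energy_window_kev: [435.0, 650.0]
n_radial: 400
n_angles: 168
n_planes: 148
radial_bin_size_mm: 1.0
recon_shape: [400, 400, 148]
recon_voxel_mm: [1.02, 1.02, 1.5]
osem_subsets: 21
osem_iterations: 2
post_filter_fwhm_mm: 3.0
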