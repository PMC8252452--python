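# GE Advance NXi (BGO). Reconstruction grid/voxel follow the clinical brain
# protocol; ring geometry, energy resolution and window are implementer
# defaults from vendor literature and may be overridden.
name: advance_nxi
ring_radius_mm: 463.5
n_rings: 18
n_crystals_per_ring: 672
crystal_axial_pitch_mm: 8.5
energy_resolution_fwhm_fraction: 0.15
energy_window_kev: [375.0, 650.0]
n_radial: 281
n_angles: 336
n_planes: 35
radial_bin_size_mm: 1.95
recon_shape: [128, 128, 35]
recon_voxel_mm: [2.05, 2.05, 4.3]
osem_subsets: 28
osem_iterations: 2
post_filter_fwhm_mm: 5.0
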