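# GE Discovery ST (BGO). Reconstruction grid/voxel follow the clinical brain
# protocol; ring geometry, energy resolution and window are implementer
# defaults from vendor literature and may be overridden.
name: discovery_st
ring_radius_mm: 443.0
n_rings: 24
n_crystals_per_ring: 420
crystal_axial_pitch_mm: 6.54
energy_resolution_fwhm_fraction: 0.15
energy_window_kev: [375.0, 650.0]
n_radial: 249
n_angles: 210
n_planes: 47
radial_bin_size_mm: 1.56
recon_shape: [128, 128, 47]
recon_voxel_mm: [1.95, 1.95, 3.27]
osem_subsets: 21
osem_iterations: 2
post_filter_fwhm_mm: 5.0
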