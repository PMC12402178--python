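# Demo run: simulate a small TIRF-style experiment and analyse it end to end.
# Kinetic values are plausible for dynamic microtubules from GMPCPP seeds;
# the two FRAP conditions use the GMPCPP / GDP off-rate medians as truth.

[run]
seed = 1

[dynamics]
n_microtubules = 50
v_growth = 2.0     # µm/min
v_shrink = 30.0    # µm/min
f_cat = 0.004      # 1/s
f_res = 0.02       # 1/s
seed_length = 2.0  # µm
duration = 600.0   # s

[optics]
pixel_size = 0.16      # µm/px
frame_interval = 2.0   # s
psf_sigma = 1.0        # px
photons_per_fluor = 200.0
background_level = 20.0
noise_model = "poisson+gaussian"
gaussian_sigma = 2.0

[frap]
n_traces_per_condition = 60
noise_sigma = 0.05
plateau = 0.8
n_prebleach = 55
n_postbleach = 150
frame_interval = 0.2   # s

[frap.conditions]
gmpcpp = 0.26  # 1/s
gdp = 1.07     # 1/s

[events]
n_per_class = 10
frame_interval = 2.0
duration = 400.0
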