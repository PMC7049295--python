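# Packaged model parameters (the fitted/estimated values the simulator ships with).
chemotaxis:
  tau0: 0.86            # s, mean run duration with no chemoeffector gradient
  tauT: 0.14            # s, mean tumble duration
  sigma_chemo_CT: 35.0  # s, chemotactic sensitivity x total receptor count (l-aspartic acid)
  Kd: 18.0              # uM, receptor dissociation constant (l-aspartic acid)
  speed: 34.0           # um/s, bacterial swimming speed
  theta_mu: 68.0        # deg, mean |bearing change| between runs
  theta_sigma: 36.0     # deg, SD of |bearing change| between runs
qs:
  A1: 3.19              # molecules/s, basal AHL production
  A2: 234.0             # molecules/s, upregulated AHL production
  H: 2.5                # Hill coefficient
  Q0: 1.87              # nM, AHL upregulation threshold
  ktr: 0.40             # molecules/s, max immature-GFP translation
  kGm: 3.02e-3          # 1/s, GFP maturation
  kdeg: 5.54            # molecules/s, max GFP degradation
  Km: 6650.0            # molecules/cell, degradation half-max
  Dsignal: 490.0        # um^2/s, AHL diffusivity in water
  Rd_per_hour: 0.108    # 1/h, first-order AHL degradation rate
  gfp_threshold: 218.0  # molecules/bacterium, activation readout
growth:
  doubling_bacteria_s: 2580.0   # 43 min, free-swimming bacteria
  doubling_biohybrid_s: 7260.0  # 121 min, NanoBEADS and particle-attached bacteria
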