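# Integration region scheme for MOSH/MOAH qNMR quantification.
# Windows and exclusions are (high_ppm, low_ppm) pairs; points are binned
# half-open (low, high] so adjacent windows never double-count a grid point.
scheme_version: "1.0"
regions:
  mosh:
    role: mosh
    ref_compound: decalin
    ref_mw: 138.25
    n_protons: 18
    windows: [[3.0, 0.2]]
    exclusions: [[1.58, 1.50]]   # residual H2O around 1.53 ppm
  moah:
    role: moah
    ref_compound: naphthalene
    ref_mw: 128.17
    n_protons: 8
    windows: [[9.20, 7.55], [7.50, 7.30], [7.22, 7.00], [6.97, 6.50]]
    exclusions: []               # CHCl3 + 13C satellites are cut out between windows
  other:
    role: other
    ref_compound: glycerol
    ref_mw: 92.09
    n_protons: 5
    windows: [[6.50, 3.00]]
    exclusions: []
  benz_a_anthracene:
    role: pah4
    ref_compound: benz[a]anthracene
    ref_mw: 228.29
    n_protons: 1
    windows: [[9.20, 9.12]]
    exclusions: []
  benzo_a_pyrene:
    role: pah4
    ref_compound: benzo[a]pyrene
    ref_mw: 252.32
    n_protons: 2
    windows: [[9.06, 8.98]]
    exclusions: []
  chrysene:
    role: pah4
    ref_compound: chrysene
    ref_mw: 228.29
    n_protons: 2
    windows: [[8.76, 8.70]]
    exclusions: []
  benzo_b_fluoranthene:
    role: pah4
    ref_compound: benzo[b]fluoranthene
    ref_mw: 252.32
    n_protons: 2
    windows: [[7.45, 7.38]]
    exclusions: []
  tcnb_s:
    role: quantref_signal
    ref_compound: tetrachloronitrobenzene
    ref_mw: 260.89
    n_protons: 1
    windows: [[7.83, 7.64]]
    exclusions: []
  ethylbenzene_m:
    role: quantref_signal
    ref_compound: ethylbenzene
    ref_mw: 106.17
    n_protons: 3
    windows: [[7.23, 7.11]]
    exclusions: []
  ethylbenzene_q:
    role: quantref_signal
    ref_compound: ethylbenzene
    ref_mw: 106.17
    n_protons: 2
    windows: [[2.75, 2.54]]
    exclusions: []
  ethylbenzene_t:
    role: quantref_signal
    ref_compound: ethylbenzene
    ref_mw: 106.17
    n_protons: 3
    windows: [[1.35, 1.13]]
    exclusions: []
  control_cyclohexane:
    role: control
    ref_compound: cyclohexane
    ref_mw: 84.16
    n_protons: 12
    windows: [[1.53, 1.36]]
    exclusions: []                # water exclusion is never applied to the control
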