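# Default parameters of the reduced four-neuron tadpole CPG.
#
# Units: capacitance pF, conductances nS, voltages mV, times ms,
# currents pA (1 nA stimulus = 1000 pA).
#
# Channel gating rates use the form (A + B*v) / (C + exp((D + v)/E))
# with A in 1/ms, B in 1/(ms*mV), C dimensionless, D and E in mV.
# The dIN kinetics derive from the experimentally constrained dIN
# spiking model of the tadpole hindbrain/spinal cord modelling
# literature; the cIN kinetics from the corresponding multi-type
# spinal neuron models.  See docs/methods.md for provenance notes.

membrane_capacitance_pF: 10.0

calcium:
  # GHK constant-field calcium current of the dIN (depolarizing-positive).
  p_ca: 14.25          # cm^3/ms permeability scale; numeric current read in pA
  faraday: 96485.0     # C/mol
  gas_constant: 8.314  # J/(K mol)
  temperature_K: 300.0
  ca_in: 1.0e-7        # mol/cm^3
  ca_out: 1.0e-5       # mol/cm^3

neurons:
  dIN:
    g_lk: 1.4
    e_lk: -52.0
    g_na: 240.5
    e_na: 50.0
    g_kf: 12.0
    e_kf: -80.0
    g_ks: 9.6
    e_ks: -80.0
    kf_power: 4
    ks_power: 2
    calcium: true
    rates:
      m:
        alpha: [8.0, 0.0, 1.0, 26.0, -6.0]
        beta: [10.0, 0.0, 1.0, 34.0, 6.0]
      h:
        alpha: [0.0975, 0.0, 0.0, 48.0, 9.0]
        beta: [1.625, 0.0, 1.0, 24.0, -6.0]
      f:
        alpha: [2.5, 0.0, 1.0, 25.0, -7.0]
        beta: [0.6, 0.0, 1.0, 25.0, 7.0]
      l:
        alpha: [0.05, 0.0, 1.0, 36.0, -6.0]
        beta: [0.05, 0.0, 1.0, 36.0, 6.0]
      r:
        alpha: [2.5, 0.0, 1.0, 43.7, -5.0]
        beta: [2.5, 0.0, 1.0, 43.7, 5.0]
  cIN:
    g_lk: 2.47
    e_lk: -61.0
    g_na: 110.0
    e_na: 50.0
    g_kf: 8.0
    e_kf: -80.0
    g_ks: 1.0
    e_ks: -80.0
    kf_power: 1
    ks_power: 1
    calcium: false
    rates:
      m:
        alpha: [13.26, 0.0, 1.0, -5.01, -12.56]
        beta: [5.73, 0.0, 1.0, 5.95, 9.69]
      h:
        alpha: [0.04, 0.0, 0.0, 15.27, 26.0]
        beta: [2.04, 0.0, 1.0, -9.09, -10.21]
      f:
        alpha: [3.10, 0.0, 1.0, -27.5, -9.3]
        beta: [0.44, 0.0, 1.0, 8.98, 16.84]
      l:
        alpha: [0.20, 0.0, 1.0, -10.96, -7.74]
        beta: [0.05, 0.0, 1.0, -22.07, 6.10]

synapses:
  nmda:
    e: 0.0
    tau_o: 0.5
    tau_c: 80.0
    vbar: 10.0
    T: 1.5
    mg_block: true
  ampa:
    e: 0.0
    tau_o: 0.2
    tau_c: 3.0
    vbar: 10.0
    T: 4.0
    mg_block: false
  glycine:
    e: -75.0
    tau_o: 1.5
    tau_c: 4.0
    vbar: 1.0
    T: 1.0
    mg_block: false

weights:
  w_ampa: 10.0
  w_nmda: 10.0
  w_inh: 30.0
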