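# Periglomerular cell: six isopotential cylindrical compartments.
#
# Maximum conductances are given as the per-compartment table (nS) of the
# fitted model; the builder distributes each current uniformly (the soma
# row divided by the soma area fixes the density, as the per-compartment
# values are area-proportional).  The dendritic-shaft/gemmule sodium value
# follows the uniform-density rule (0.484 nS); one printed source carries
# a dropped-digit misprint (0.0484) there.
#
# Passive constants and the autapse conductance are calibration values
# chosen to reproduce the fitted cell's response (single low-threshold
# spike followed by a depolarized plateau under a 100 pA / 600 ms somatic
# step, input resistance near 1 GOhm); see docs/methods.md.

cell: pg
geometry:
  - {name: soma, length_um: 8.0, diameter_um: 8.0, parent: null}
  - {name: axon, length_um: 50.0, diameter_um: 1.0, parent: soma}
  - {name: dendrite1, length_um: 20.0, diameter_um: 1.0, parent: soma}
  - {name: dendrite2, length_um: 20.0, diameter_um: 1.0, parent: soma}
  - {name: shaft, length_um: 1.0, diameter_um: 1.0, parent: dendrite1}
  - {name: gemmule, length_um: 1.0, diameter_um: 1.0, parent: shaft}

passive:
  axial_resistivity: 150.0      # Ohm*cm
  specific_capacitance: 1.0     # uF/cm^2
  leak_conductance_density: 6.0e-4  # S/cm^2
  leak_reversal: -77.0          # mV
  resting_potential: -77.0      # mV initial value (settles near -76;
                                # hyperpolarized rest keeps the T-type
                                # current partly de-inactivated)

column_order: [H, K, Na, KA, CaT]
channel_map:
  H: pg_h
  K: pg_kdr
  Na: pg_na
  KA: pg_ka
  CaT: pg_cat

conductances_nS:
  soma:      {H: 0.101, K: 44.420, Na: 30.950, KA: 61.850, CaT: 9.723}
  axon:      {H: 0.079, K: 34.690, Na: 24.180, KA: 48.310, CaT: 7.595}
  dendrite1: {H: 0.031, K: 13.880, Na: 9.671, KA: 19.320, CaT: 3.038}
  dendrite2: {H: 0.031, K: 13.880, Na: 9.671, KA: 19.320, CaT: 3.038}
  shaft:     {H: 0.002, K: 0.694, Na: 0.484, KA: 0.966, CaT: 0.152}
  gemmule:   {H: 0.002, K: 0.694, Na: 0.484, KA: 0.966, CaT: 0.152}

autapse:
  site: gemmule
  gmax: 0.016       # uS, calibrated: single spike with the fitted delay
  reversal: -80.0
  threshold: -38.0
  slope: 6.0        # shallower than the circuit synapses; the autapse
                    # senses the locally depolarized gemmule
  tau: 1.0

calcium_pool:
  shell_depth_um: 1.0
  removal_tau_ms: 5.0
  resting_mM: 2.4e-4
  external_mM: 2.0
  floor_mM: 1.0e-8
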