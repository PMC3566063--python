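# Ionic-channel kinetics catalog.
#
# Each entry declares the gates of one channel kind.  A gate is either
#   - alpha/beta rate pair (kinds: linoid, expo, sigmoid, const), with
#       linoid:  a*(v-vh)/(1-exp(-(v-vh)/k))
#       expo:    a*exp((v-vh)/k)
#       sigmoid: a/(1+exp(-(v-vh)/k))
#   - an {inf: {vh,k}, tau: {form,...}} pair where inf is a Boltzmann
#     sigmoid and tau one of: const, dualexp
#     (base + scale/(exp((v-vh1)/k1)+exp((v-vh2)/k2))), cat_h (piecewise
#     T-current inactivation), linear_min
#   - a named special form (ka_thermo_act / ka_thermo_inact / ca_linear).
#
# Voltages mV, times ms, rates 1/ms, densities S/cm^2.
#
# Periglomerular set: Traub-type Na/K rates (voltage origin shifted so the
# spike threshold sits near -45 mV), thermodynamic A-current, HCN h-current,
# and the low-threshold T-type calcium current with a Nernstian reversal
# fed by a submembrane calcium shell.

pg_na:
  reversal: 50.0
  gates:
    - power: 3
      alpha: {kind: linoid, a: 0.32, vh: -42.0, k: 4.0}
      beta: {kind: linoid, a: -0.28, vh: -15.0, k: -5.0}
    - power: 1
      alpha: {kind: expo, a: 0.128, vh: -38.0, k: -18.0}
      beta: {kind: sigmoid, a: 4.0, vh: -15.0, k: 5.0}

pg_kdr:
  reversal: -90.0
  gates:
    - power: 2
      alpha: {kind: linoid, a: 0.016, vh: -35.0, k: 5.0}
      beta: {kind: expo, a: 0.25, vh: -40.0, k: -40.0}

# A-type current calibrated as the latency mechanism of the fitted cell:
# fast low-threshold activation with slow inactivation transiently clamps
# the depolarization below the low-threshold-spike ignition point.
pg_ka:
  reversal: -90.0
  gates:
    - power: 1
      inf: {vh: -45.0, k: 4.0}
      tau: {form: const, value: 8.0}
    - power: 1
      inf: {vh: -65.0, k: -2.0}
      tau: {form: const, value: 12.0}

pg_h:
  reversal: -35.0
  gates:
    - power: 1
      inf: {vh: -80.0, k: -8.0}
      tau: {form: dualexp, base: 0.0, scale: 1.0,
            vh1: -169.6512, k1: -11.6279, vh2: 26.6757, k2: 14.2653}

# T-type calcium current: activation shifted/slowed and availability
# raised relative to the thalamic formulation so that a depolarizing step
# from rest evokes a delayed low-threshold spike (the phenotype of the
# recorded juxtaglomerular cells); see docs/methods.md.
pg_cat:
  reversal: nernst-ca
  feeds_calcium: true
  gates:
    - power: 2
      inf: {vh: -50.0, k: 6.2}
      tau: {form: dualexp, base: 0.918, scale: 1.5,
            vh1: -132.0, k1: -16.7, vh2: -16.8, k2: 18.2}
    - power: 1
      inf: {vh: -68.0, k: -4.0}
      tau: {form: cat_h, scale: 1.5}

# Mitral set (Bhalla-Bower/Davison lineage): fast Na, fast and slow
# delayed rectifiers, A-type and calcium-activated K, and a high-threshold
# calcium current with fixed reversal that loads the calcium shell.

mit_na:
  reversal: 45.0
  gates:
    - power: 3
      alpha: {kind: linoid, a: 0.32, vh: -49.0, k: 4.0}
      beta: {kind: linoid, a: -0.28, vh: -22.0, k: -5.0}
    - power: 1
      alpha: {kind: expo, a: 0.128, vh: -45.0, k: -18.0}
      beta: {kind: sigmoid, a: 4.0, vh: -22.0, k: 5.0}

mit_kfast:
  reversal: -70.0
  gates:
    - power: 2
      alpha: {kind: linoid, a: 0.032, vh: -32.0, k: 5.0}
      beta: {kind: expo, a: 0.5, vh: -37.0, k: -40.0}

mit_ks:
  reversal: -70.0
  gates:
    - power: 1
      inf: {vh: -25.0, k: 4.0}
      tau: {form: dualexp, base: 8.0, scale: 50.0,
            vh1: -55.0, k1: 20.0, vh2: -55.0, k2: -20.0}

mit_ka:
  reversal: -70.0
  gates:
    - power: 1
      inf: {vh: -35.0, k: 10.0}
      tau: {form: const, value: 1.4}
    - power: 1
      inf: {vh: -75.0, k: -6.0}
      tau: {form: const, value: 25.0}

mit_kca:
  reversal: -70.0
  gates:
    - power: 1
      form: ca_linear
      params: {a: 2.0, b: 0.5}

mit_lca:
  reversal: 70.0
  feeds_calcium: true
  gates:
    - power: 1
      alpha: {kind: sigmoid, a: 7.5, vh: 13.0, k: 7.0}
      beta: {kind: sigmoid, a: 1.65, vh: 14.0, k: -4.0}

# Granule set: fast Na and delayed rectifier, A-type K, and a slow
# non-inactivating M-type K current.

grc_na:
  reversal: 45.0
  gates:
    - power: 3
      alpha: {kind: linoid, a: 0.32, vh: -43.0, k: 4.0}
      beta: {kind: linoid, a: -0.28, vh: -16.0, k: -5.0}
    - power: 1
      alpha: {kind: expo, a: 0.128, vh: -39.0, k: -18.0}
      beta: {kind: sigmoid, a: 4.0, vh: -16.0, k: 5.0}

grc_kdr:
  reversal: -70.0
  gates:
    - power: 2
      alpha: {kind: linoid, a: 0.032, vh: -32.0, k: 5.0}
      beta: {kind: expo, a: 0.5, vh: -37.0, k: -40.0}

grc_ka:
  reversal: -70.0
  gates:
    - power: 1
      inf: {vh: -35.0, k: 10.0}
      tau: {form: const, value: 1.4}
    - power: 1
      inf: {vh: -75.0, k: -6.0}
      tau: {form: const, value: 25.0}

grc_km:
  reversal: -70.0
  gates:
    - power: 1
      inf: {vh: -45.0, k: 6.0}
      tau: {form: dualexp, base: 0.0, scale: 1.0,
            vh1: 79.2768, k1: 20.0, vh2: -149.2768, k2: -20.0}
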