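# Default kinetic rate constants for the receptor activation model, v1.
#
# Units: time in ms, glutamate concentration in uM, voltage in mV.
# Scheme topology is fixed in code (two sequential glutamate binding steps,
# an open state, AMPA desensitization from the doubly-bound closed state,
# NMDA open-channel Mg block); every rate below is a configuration entry
# with a representative default.  AMPA values are in the range of published
# fast-synapse gating models (association ~5e6 /M/s, fast gating, slow
# recovery from desensitization); NMDA values give the slow deactivation and
# a singly-bound dwell time of tens of milliseconds that make delayed release
# effective.  The Mg block equilibrium follows the classic ~e-fold / 16 mV
# voltage dependence with ~95% block at -70 mV in 1 mM Mg2+.
ampa:
  kon_per_uM_ms: 0.010      # glutamate association, per binding site
  koff_per_ms: 4.3          # glutamate dissociation
  beta_per_ms: 4.2          # channel opening from doubly-bound closed
  alpha_per_ms: 0.9         # channel closing
  kdes_per_ms: 1.0          # desensitization from doubly-bound closed
  krec_per_ms: 0.015        # recovery from desensitization (~67 ms)
nmda:
  kon_per_uM_ms: 0.015
  koff1_per_ms: 0.015       # singly-bound unbinding; dwell ~67 ms primes
                            # the receptor for delayed release
  koff2_per_ms: 0.15        # doubly-bound unbinding; keeps the open burst
                            # within the depolarization window
  beta_per_ms: 0.3
  alpha_per_ms: 0.25
mg_block:
  mg_mM: 1.0
  k_block0_per_mM_ms: 2.8   # block rate at 0 mV per mM Mg2+
  k_unblock0_per_ms: 10.0   # unblock rate at 0 mV
  v_block_slope_mV: 28.0    # block rate e-folds per this depolarization
  v_unblock_slope_mV: 38.0  # unblock rate e-folds per this depolarization
glutamate:
  n_glu: 2000.0             # molecules per vesicle
  cleft_height_nm: 20.0
  D_um2_per_ms: 0.3
  tau_clear_ms: 1.0         # stands in for astrocytic transporter uptake
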