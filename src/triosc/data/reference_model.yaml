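# Reference configuration of the mTORC1-AMPK-ULK1 autophagy-induction model.
#
# Rate constants k_* have dimension 1/time; Michaelis constants J_* and the
# stress inputs are dimensionless; pool totals and activities are in a.u.
# The set was calibrated so that the unstressed cell rests at a unique stable
# steady state with high mTORC1 and autophagy off, while cellular stress
# (stress = 0.75, stress1 = 0.25) or rapamycin treatment (mTORC1 total
# lowered to 0.4) puts the amplified-negative-feedback wiring (variant A)
# on a sustained limit cycle, and the variant amplitude ordering
# B < C < A < D holds.
species:
  mTORC1:    {total: 1.0, initial_activity: 0.0}
  AMPK:      {total: 1.0, initial_activity: 0.0}
  ULK1:      {total: 1.0, initial_activity: 0.0}
  PROT:      {total: 1.0, initial_activity: 0.0}
  AUTOPHAGY: {total: 1.0, initial_activity: 0.0}
parameters:
  rate_constants:
    # basal activation / inactivation per species
    k_act_mTORC1: 1.3        # basal mTORC1 (re)activation; keeps mTORC1 high at rest
    k_inact_mTORC1: 0.056    # basal mTORC1 turnover
    k_act_AMPK: 0.58         # basal AMPK activation (stress adds on top)
    k_inact_AMPK: 0.039      # basal AMPK inactivation
    k_act_ULK1: 0.0007       # basal ULK1 activation (essentially PROT-driven)
    k_inact_ULK1: 0.029      # basal ULK1 inactivation; slow, ULK1 is the memory variable
    k_act_PROT: 0.05         # basal production of the delayed intermediate
    k_inact_PROT: 0.93       # PROT decay; fast so PROT tracks AMPK
    k_act_AUTOPHAGY: 0.0     # autophagy strictly requires AMPK*ULK1
    k_inact_AUTOPHAGY: 0.2   # basal autophagy shut-off
    # edge weights (loop 1: AMPK/mTORC1 double negative)
    k_ampk_mtorc1: 1.19      # AMPK -| mTORC1
    k_mtorc1_ampk: 1.07      # mTORC1 -| AMPK
    # loop 2: ULK1/mTORC1 mutual antagonism
    k_ulk1_mtorc1: 0.86      # ULK1 -| mTORC1
    k_mtorc1_ulk1: 0.056     # mTORC1 -| ULK1
    # loop 3: delayed negative feedback + amplifying double negative
    k_ampk_prot: 1.88        # AMPK -> PROT (delayed positive arm, step 1)
    k_prot_ulk1: 0.42        # PROT -> ULK1 (delayed positive arm, step 2)
    k_ulk1_ampk: 2.16        # ULK1 -| AMPK (closes the delayed negative loop)
    k_ampk_ulk1_inh: 0.26    # AMPK -| ULK1 (optional; the amplifying arm, variant A)
    k_ampk_ulk1_act: 0.36    # AMPK -> ULK1 (optional; counter-operating, variant C)
    k_ulk1_ampk_act: 0.21    # ULK1 -> AMPK (optional; variant D positive loop)
    # readout
    k_ampkulk1_auto: 4.0     # AMPK*ULK1 -> AUTOPHAGY (both required)
    k_mtorc1_auto: 1.0       # mTORC1 -| AUTOPHAGY
  michaelis_constants:
    J_act_mTORC1: 0.04       # graded mTORC1 response (source of AMPK self-gain)
    J_inact_mTORC1: 0.04
    J_act_AMPK: 0.01         # sharp, switch-like AMPK response
    J_inact_AMPK: 0.01
    J_act_ULK1: 0.01         # sharp ULK1 switch
    J_inact_ULK1: 0.01
    J_act_PROT: 0.05
    J_inact_PROT: 0.05
    J_act_AUTOPHAGY: 0.05
    J_inact_AUTOPHAGY: 0.05
  stress: 0.0                # cellular-stress input into AMPK activation
  stress1: 0.0               # cellular-stress input into mTORC1 inactivation
  totals:
    mTORC1: 1.0              # mTORC1T; set to 0.4 for the rapamycin scenario
variant:
  id: A                      # amplified negative feedback (reference wiring)
stress_points:
  stress: [AMPK, activation]
  stress1: [mTORC1, inactivation]
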