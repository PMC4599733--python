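# Dynamic Energy Budget parameters for Odontaster validus.
# Rates and costs are stated at the reference temperature Tref = 285 K.
# Units: energy J, length cm, volume cm3, mass g, time d, temperature K.

# temperature sensitivity (five-parameter Arrhenius response)
TA: 5303.0
TL: 269.5
TH: 288.0
TAL: 120200.0
TAH: 68360.0
Tref: 285.0

# primary energy-budget parameters
pAm: 6.82        # J d-1 cm-2
pM_vol: 6.93     # J d-1 cm-3
EG: 2579.0       # J cm-3
kappa: 0.81
v_dot: 0.007     # cm d-1
kJ_dot: 0.001    # d-1
delta_M: 0.57
delta_M_lrv: 0.59
kappa_R: 0.95
f_f: 0.80

# conversion couplers
dV: 1.0          # g cm-3
rho_E: 4.35e-05  # g J-1
wE: 23.9         # g mol-1
mu_E: 550.0      # kJ mol-1

# calibrated quantities (filled by `debstar calibrate` / calibration.calibrate)
d_dw: null
EHb: null
EHj: null
EHp: null
s_M: null
Lb_struct: null
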