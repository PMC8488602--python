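# Exchange-reaction flux bounds (mmol/gDW/h) per growth condition.
# Negative lower bounds permit uptake; upper bounds permit secretion.
# Non-mixotrophic conditions keep organic-carbon uptake closed
# (EX_GLYC lower bound 0). Photon lower bounds encode the light
# availability of each culture; dark conditions use -0.003 and the
# low-O2 / anoxic conditions clamp the O2 exchange to [-0.01, -0.01].
defaults:
  lb:
    EX_CO2: -10
    EX_GLYC: 0
    EX_SO4: -1000
    EX_NO3: -1000
    EX_NH4: -1000
    EX_UREA: -1000
    EX_PHOTON: -0.065
    EX_O2: -1000
    EX_FE: -1000
  ub:
    EX_PHOTON: 1000
    EX_O2: 1000
conditions:
  - name: Darkoxic
    lb: {EX_PHOTON: -0.003}
  - name: Darkanoxic
    lb: {EX_PHOTON: -0.003, EX_O2: -0.01}
    ub: {EX_O2: -0.01}
  - name: Highlight
    lb: {EX_PHOTON: -0.234}
  - name: OD04
    lb: {EX_PHOTON: -0.114}
  - name: OD10
    lb: {EX_PHOTON: -0.045}
  - name: OD30
    lb: {EX_PHOTON: -0.008}
  - name: OD50
    lb: {EX_PHOTON: -0.004}
  - name: lowO2
    lb: {EX_O2: -0.01}
    ub: {EX_O2: -0.01}
  - name: lowCO2
    lb: {EX_CO2: -0.01}
  - name: Nlim
    lb: {EX_NO3: -0.01}
  - name: Slim
    lb: {EX_SO4: -0.01}
  - name: Plim
    lb: {}
  - name: Felim
    lb: {EX_FE: -0.01}
  - name: Nitrate
    lb: {EX_NO3: -12}
  - name: Ammonia
    lb: {EX_NO3: 0, EX_NH4: -10}
  - name: Urea
    lb: {EX_NO3: 0, EX_UREA: -10}
  - name: Heatshock
    lb: {}
  - name: T22
    lb: {}
  - name: T30
    lb: {}
  - name: Oxstress
    lb: {}
  - name: Mixotrophic
    lb: {EX_GLYC: -10}
  - name: Lowsalt
    lb: {}
  - name: Highsalt
    lb: {}
  - name: Standardcontrol
    lb: {}
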