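# A physiological-model scenario at low production with explicit rates,
# for `glycoqc steady-state --scenario examples/scenario.yaml`.
variant: PHYS
conditions: {kpt: 0.1, mf: 0.001, kf: 1.0, Pb: 1.0}
rates: {kc: 100.0, kg: 10.0, kmg: 0.01, kd: 0.1}
seed: 0
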