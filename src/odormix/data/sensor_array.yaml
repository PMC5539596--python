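# Synthetic default gas-sensor array for simulation.
#
# The qualitative response pattern (which sensor responds to which
# aldehyde) follows the published screening of this seven-sensor array:
#   acetaldehyde (A):      MQ6, MS1100, TGS2610
#   propionaldehyde (P):   WSP2620, MQ6, MP502 (weak), TGS2610
#   n-butyraldehyde (B):   MQ6, TGS2602, MP502 (strong), MC119
# Sensitivity magnitudes (signal units per mg/m^3) and baselines are
# invented for simulation; real response curves are not reproduced here.
sensors:
  - name: TGS2602
    baseline: 0.20
    sensitivities: {n-Butyraldehyde: 2.4}
  - name: TGS2610
    baseline: 0.25
    sensitivities: {Acetaldehyde: 1.1, Propionaldehyde: 1.6}
  - name: MQ6
    baseline: 0.30
    sensitivities: {Acetaldehyde: 2.8, Propionaldehyde: 1.9, n-Butyraldehyde: 1.2}
  - name: MC119
    baseline: 0.15
    sensitivities: {n-Butyraldehyde: 1.7}
  - name: MP502
    baseline: 0.22
    sensitivities: {Propionaldehyde: 0.6, n-Butyraldehyde: 2.9}
  - name: MS1100
    baseline: 0.18
    sensitivities: {Acetaldehyde: 2.1}
  - name: WSP2620
    baseline: 0.28
    sensitivities: {Propionaldehyde: 2.5}
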