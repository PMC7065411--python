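# Published body-weight prediction equation using heart girth (HG) and
# belly girth (BG).  Units: intercept/effects kg, slopes kg per cm, stage
# curves kg with polynomial coefficients in ascending powers of the day
# relative to calving (lactation: DIM 1-364; dry: day -56..-1).
name: model_hgbg
intercept: -724.81
genotype_effect:
  FV: -101.07
  FV_RH_m: -121.05
  FV_RH_h: -148.33
  HF: -16.418
  BS: 0.0
parity_effect:
  P1: -16.797
  P2: -7.0643
  P3_4: -0.9199
  P5plus: 0.0
pooled_slope:
  HG: 3.1643
  BG: 2.9949
genotype_slope:
  HG:
    FV: 1.0631
    FV_RH_m: 1.1516
    FV_RH_h: 0.716
    HF: -0.0485
    BS: 0.0
  BG:
    FV: -0.3853
    FV_RH_m: -0.3985
    FV_RH_h: -0.01813
    HF: 0.00439
    BS: 0.0
lactation_curve:
- 2.7426
- -0.324907
- 0.00231406
- -5.67999e-06
- 4.74719e-09
dry_curve:
- 18.755
- 0.254644
model_spec:
- HG
- BG
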