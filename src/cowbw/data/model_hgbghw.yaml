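# Published body-weight prediction equation using heart girth (HG), belly
# girth (BG) and hip width (HW).  Units: intercept/effects kg, slopes kg per
# cm, stage curves kg with polynomial coefficients in ascending powers of
# the day relative to calving (lactation: DIM 1-364; dry: day -56..-1).
name: model_hgbghw
intercept: -833.39
genotype_effect:
  FV: -79.985
  FV_RH_m: -133.55
  FV_RH_h: -121.77
  HF: 0.7205
  BS: 0.0
parity_effect:
  P1: -9.4629
  P2: -4.6182
  P3_4: -2.2144
  P5plus: 0.0
pooled_slope:
  HG: 2.5192
  BG: 2.903
  HW: 4.7367
genotype_slope:
  HG:
    FV: 0.9442
    FV_RH_m: 1.2656
    FV_RH_h: 0.8393
    HF: 0.00328
    BS: 0.0
  BG:
    FV: -0.4459
    FV_RH_m: -0.475
    FV_RH_h: -0.0904
    HF: 0.03483
    BS: 0.0
  HW:
    FV: 0.3378
    FV_RH_m: 0.1046
    FV_RH_h: -0.6885
    HF: -0.6804
    BS: 0.0
lactation_curve:
- -0.390321
- -0.00278743
- 0.00231406
- -7.38974e-06
- 7.23071e-09
dry_curve:
- 17.2602
- 0.226024
model_spec:
- HG
- BG
- HW
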