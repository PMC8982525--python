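# Pharmacophore model Hypo(8-R3-08)
# 4 features (HBA, HBD, Hbic, RingArom), no exclusion spheres
MODEL Hypo(8-R3-08)
WEIGHT 2.18
FEATURE HBA 4.51 -2.27 0.06 1.60 PROJ 3.65 -5.16 -0.07 2.20
FEATURE HBD -2.13 -1.90 2.84 1.60 PROJ 0.73 -2.75 3.13 2.20
FEATURE HBIC -3.08 -3.82 6.66 1.60
FEATURE RAROM -1.42 0.01 -0.01 1.60 PROJ -1.42 2.60 1.50 1.60
END
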