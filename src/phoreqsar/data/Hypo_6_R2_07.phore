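# Pharmacophore model Hypo(6-R2-07)
# 4 features (HBA, HBD, Hbic, RingArom), 4 exclusion spheres (1.2 A diameter)
MODEL Hypo(6-R2-07)
WEIGHT 1.97
FEATURE HBA -1.37 -1.58 -1.25 1.60 PROJ -0.27 -2.36 -3.93 2.20
FEATURE HBD -2.84 -1.35 -2.47 1.60 PROJ -4.35 -3.68 -3.62 2.20
FEATURE HBIC -0.56 0.70 -4.49 1.60
FEATURE RAROM 2.23 -1.44 0.53 1.60 PROJ 2.82 1.38 -0.31 1.60
EXCLUDE -1.81 2.02 -7.37 0.60
EXCLUDE 2.94 1.12 2.95 0.60
EXCLUDE -3.64 -0.13 4.64 0.60
EXCLUDE 3.49 -5.94 0.08 0.60
END
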