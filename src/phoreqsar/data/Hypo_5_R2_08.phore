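# Pharmacophore model Hypo(5-R2-08)
# 4 features (HBA, Hbic, Hbic, RingArom), 3 exclusion spheres (1.2 A diameter)
MODEL Hypo(5-R2-08)
WEIGHT 2.26
FEATURE HBA 5.60 -0.30 -0.002 1.60 PROJ 7.80 1.78 -0.04 2.20
FEATURE HBIC 2.93 -1.08 4.00 1.60
FEATURE HBIC -0.72 -0.82 6.46 1.60
FEATURE RAROM -3.62 -0.86 0.39 1.60 PROJ -3.80 1.75 1.86 1.60
EXCLUDE -1.73 -0.05 9.32 0.60
EXCLUDE 4.58 0.33 2.75 0.60
EXCLUDE 3.06 3.54 -2.21 0.60
END
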