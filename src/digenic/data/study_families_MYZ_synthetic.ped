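# Three multigeneration myopathy families (M, Y, Z) reconstructed from the
# member-by-member descriptions in the study text and figure legend.
# SYNTHETIC STAND-IN: every named individual's sex, affection, two-locus
# carrier status and X-inactivation call follows the published description;
# the connecting structure (unnamed spouses/ancestors) is inferred, since no
# machine-readable pedigrees are published.
#FID IID FAT MOT SEX PHENO S_OBS T_OBS XI PROBAND
M MI:1 0 0 1 0 0 0 0 0
M MI:2 0 0 2 1 2 0 0 0
M MII:1 0 0 1 1 1 2 0 0
M MII:2 MI:1 MI:2 2 1 2 1 1 0
M MIII:2 MII:1 MII:2 1 1 1 2 0 0
M MIII:3 MII:1 MII:2 1 2 3 2 0 1
Y YI:1 0 0 1 1 1 2 0 0
Y YI:2 0 0 2 1 2 0 0 0
Y YII:1 0 0 1 1 1 1 0 0
Y YII:2 YI:1 YI:2 2 1 2 2 1 0
Y YII:3 YI:1 YI:2 1 2 3 2 0 1
Y YIII:3 0 0 1 1 1 1 0 0
Y YIII:4 YII:1 YII:2 2 2 2 2 2 0
Y YIII:5 YII:1 YII:2 2 2 2 2 2 0
Y YIV:1 YIII:3 YIII:4 1 1 3 1 0 0
Z ZI:1 0 0 1 0 0 0 0 0
Z ZI:2 0 0 2 1 2 0 0 0
Z ZII:1 0 0 1 1 1 2 0 0
Z ZII:2 ZI:1 ZI:2 2 1 2 0 0 0
Z ZII:5 ZI:1 ZI:2 2 1 2 1 3 0
Z ZIII:2 ZII:1 ZII:2 1 1 3 1 0 0
Z ZIII:4 ZII:1 ZII:2 1 2 3 2 0 1
Z ZIII:5 ZII:1 ZII:2 2 1 2 2 1 0
Z ZIII:6 0 0 1 1 1 1 0 0
Z ZIII:7 ZII:1 ZII:2 1 2 3 2 0 0
Z ZIII:8 0 0 2 1 1 1 0 0
Z ZIV:1 ZIII:6 ZIII:5 1 2 3 2 0 0
Z ZIV:4 ZIII:7 ZIII:8 1 1 1 2 0 0
Z ZIV:6 ZIII:7 ZIII:8 1 1 1 2 0 0
Z ZIV:7 ZIII:7 ZIII:8 1 1 1 2 0 0
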