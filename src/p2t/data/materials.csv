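name,density_g_cm3,composition
air,0.0012,N:0.755 O:0.232 Ar:0.013
water,1.00,H:0.111894 O:0.888106
lung_inhale,0.26,H:0.103 C:0.105 N:0.031 O:0.749 Na:0.002 P:0.002 S:0.003 Cl:0.003 K:0.002
lung_exhale,0.50,H:0.103 C:0.105 N:0.031 O:0.749 Na:0.002 P:0.002 S:0.003 Cl:0.003 K:0.002
adipose,0.95,H:0.114 C:0.598 N:0.007 O:0.278 Na:0.001 S:0.001 Cl:0.001
breast,0.99,H:0.109 C:0.506 N:0.023 O:0.358 Na:0.001 P:0.001 S:0.001 Cl:0.001
muscle,1.05,H:0.102 C:0.143 N:0.034 O:0.710 Na:0.001 P:0.002 S:0.003 Cl:0.001 K:0.004
liver,1.06,H:0.102 C:0.139 N:0.030 O:0.716 Na:0.002 P:0.003 S:0.003 Cl:0.002 K:0.003
trabecular_bone,1.18,H:0.085 C:0.404 N:0.028 O:0.367 Na:0.001 Mg:0.001 P:0.034 S:0.002 Cl:0.002 K:0.001 Ca:0.074 Fe:0.001
dense_bone,1.92,H:0.034 C:0.155 N:0.042 O:0.435 Na:0.001 Mg:0.002 P:0.103 S:0.003 Ca:0.225
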