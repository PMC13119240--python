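name: vinylpyrrolidone
conformer_id: monomer
atoms:
- [CB1, C, C_CH3_CH2, -2.2581, 0.8601, 0.4555]
- [CB2, C, C_CH3_CH2, -1.6739, -0.4729, 0.0182]
- [CC, C, C_R2CO, 0.5967, -0.6263, 1.0446]
- [CR1, C, default, 0.4755, 0.2038, -1.1405]
- [CR2, C, default, 1.9217, -0.1636, -0.8759]
- [CR3, C, default, 2.0004, -0.2391, 0.6444]
- [NR, N, default, -0.2253, -0.4447, -0.0618]
- [OC, O, O_R2CO, 0.2544, -0.9832, 2.1596]
- [HB1a, H, default, -3.3478, 0.7916, 0.5285]
- [HB1b, H, default, -1.867, 1.1606, 1.433]
- [HB1c, H, default, -2.0142, 1.6521, -0.2598]
- [HB2a, H, default, -1.9629, -1.2438, 0.7412]
- [HB2c, H, default, -2.0657, -0.7648, -0.9617]
- [HR1, H, default, 0.3184, 1.285, -1.0677]
- [HR2, H, default, 0.1211, -0.1633, -2.1074]
- [HR3, H, default, 2.6288, 0.5515, -1.3052]
- [HR4, H, default, 2.1394, -1.1511, -1.3019]
- [HR5, H, default, 2.7235, -0.9881, 0.9756]
- [HR6, H, default, 2.2351, 0.7363, 1.0814]
bonds:
- [CB1, CB2]
- [CB1, HB1a]
- [CB1, HB1b]
- [CB1, HB1c]
- [CB2, HB2a]
- [CB2, HB2c]
- [CB2, NR]
- [CC, CR3]
- [CC, NR]
- [CC, OC]
- [CR1, CR2]
- [CR1, HR1]
- [CR1, HR2]
- [CR1, NR]
- [CR2, CR3]
- [CR2, HR3]
- [CR2, HR4]
- [CR3, HR5]
- [CR3, HR6]
rotatable_groups: []
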