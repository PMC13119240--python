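name: nifedipine
conformer_id: flipped
atoms:
- [C10A, C, C_CH3OR, 4.2975, -0.9047, -1.5504]
- [C10B, C, C_CH3OR, -2.8259, 2.7384, 2.1329]
- [C2, C, C_pyridine_NIF, 0.0572, -1.1635, -2.0735]
- [C3, C, C_pyridine_NIF, 0.7255, -0.2014, -1.3963]
- [C4, C, C_pyridine_NIF, 0.0072, 0.7397, -0.4206]
- [C5, C, C_pyridine_NIF, -1.5093, 0.5803, -0.4714]
- [C6, C, C_pyridine_NIF, -2.0956, -0.419, -1.1685]
- [C7, C, C_CH3_CH2, 0.6739, -2.0746, -3.1043]
- [C8, C, C_CH3_CH2, -3.5848, -0.6372, -1.2626]
- [C9A, C, C_R2CO, 2.1753, 0.0629, -1.5321]
- [C9B, C, C_R2CO, -2.3356, 1.6439, 0.135]
- [CA1, C, default, 0.9208, -0.7554, 3.039]
- [CA2, C, default, 1.5358, 0.3367, 3.6401]
- [CA3, C, default, 1.6722, 1.5298, 2.94]
- [CA4, C, default, 1.1937, 1.6307, 1.6388]
- [CA5, C, default, 0.5787, 0.5386, 1.0378]
- [CA6, C, C_CNO2, 0.4423, -0.6544, 1.7379]
- [N1, N, N_NHR, -1.3073, -1.3201, -1.8704]
- [N2, N, N_CNO2, -0.2081, -1.8094, 1.1023]
- [O1A, O, O_ROR, 2.8826, -1.0933, -1.5121]
- [O1B, O, O_ROR, -2.0935, 1.711, 1.4654]
- [O2A, O, O_R2CO, 2.6439, 1.1906, -1.5552]
- [O2B, O, O_R2CO, -3.138, 2.3203, -0.4898]
- [O3A, O, O_CNO2, 0.2215, -2.1942, 0.0066]
- [O3B, O, O_CNO2, -1.0582, -2.3967, 1.785]
- [H1, H, default, 4.7707, -1.8905, -1.543]
- [H10, H, default, -2.5196, 2.7444, 3.1826]
- [H11, H, default, -2.5988, 3.7184, 1.7015]
- [H12, H, default, -3.8998, 2.5329, 2.0857]
- [H13, H, default, 0.2133, 1.7501, -0.7892]
- [H14, H, default, 1.3006, 2.5663, 1.0898]
- [H15, H, default, 2.1544, 2.3862, 3.4113]
- [H16, H, default, 1.9111, 0.2576, 4.6604]
- [H17, H, default, 0.8139, -1.6909, 3.588]
- [H1N, H, H_NHR, -1.7948, -1.9655, -2.4887]
- [H2, H, default, 4.5913, -0.3865, -2.4686]
- [H3, H, default, 4.634, -0.3522, -0.6674]
- [H4, H, default, 0.9268, -3.0391, -2.6528]
- [H5, H, default, -0.0285, -2.2573, -3.9257]
- [H6, H, default, 1.5711, -1.6493, -3.5629]
- [H7, H, default, -4.1493, -0.0983, -0.4967]
- [H8, H, default, -3.9493, -0.3257, -2.2468]
- [H9, H, default, -3.8189, -1.6998, -1.1313]
bonds:
- [C10A, H1]
- [C10A, H2]
- [C10A, H3]
- [C10A, O1A]
- [C10B, H10]
- [C10B, H11]
- [C10B, H12]
- [C10B, O1B]
- [C2, C3]
- [C2, C7]
- [C2, N1]
- [C3, C4]
- [C3, C9A]
- [C4, C5]
- [C4, CA5]
- [C4, H13]
- [C5, C6]
- [C5, C9B]
- [C6, C8]
- [C6, N1]
- [C7, H4]
- [C7, H5]
- [C7, H6]
- [C8, H7]
- [C8, H8]
- [C8, H9]
- [C9A, O1A]
- [C9A, O2A]
- [C9B, O1B]
- [C9B, O2B]
- [CA1, CA2]
- [CA1, CA6]
- [CA1, H17]
- [CA2, CA3]
- [CA2, H16]
- [CA3, CA4]
- [CA3, H15]
- [CA4, CA5]
- [CA4, H14]
- [CA5, CA6]
- [CA6, N2]
- [H1N, N1]
- [N2, O3A]
- [N2, O3B]
rotatable_groups:
- axis: [C3, C9A]
  moved: [C10A, H1, H2, H3, O1A, O2A]
- axis: [C5, C9B]
  moved: [C10B, H10, H11, H12, O1B, O2B]
- axis: [C2, C7]
  moved: [H4, H5, H6]
- axis: [C6, C8]
  moved: [H7, H8, H9]
- axis: [CA6, N2]
  moved: [O3A, O3B]
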