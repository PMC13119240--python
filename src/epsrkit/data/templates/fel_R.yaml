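name: felodipine
conformer_id: R
atoms:
- [C10A, C, C_CH3OR, 3.9876, 0.0835, -1.369]
- [C10B, C, C_CH3OR, -4.9713, 0.5695, 0.4088]
- [C11A, C, C_CH3_CH2, 5.2344, -0.0269, -0.5119]
- [C2, C, C_pyridine_FEL, 1.0538, -1.2989, 1.461]
- [C3, C, C_pyridine_FEL, 1.0146, -0.1562, 0.7388]
- [C4, C, C_pyridine_FEL, -0.2847, 0.6124, 0.534]
- [C5, C, C_pyridine_FEL, -1.4812, -0.033, 1.2224]
- [C6, C, C_pyridine_FEL, -1.3564, -1.18, 1.9281]
- [C7, C, C_CH3_CH2, 2.3065, -2.0799, 1.763]
- [C8, C, C_CH3_CH2, -2.4733, -1.8448, 2.6903]
- [C9A, C, C_R2CO, 2.2115, 0.4682, 0.1408]
- [C9B, C, C_R2CO, -2.7488, 0.7148, 1.1032]
- [CA1, C, default, -1.03, 0.3873, -3.2695]
- [CA2, C, default, -1.0266, 1.7377, -3.599]
- [CA3, C, default, -0.79, 2.6922, -2.6167]
- [CA4, C, default, -0.5567, 2.2964, -1.3049]
- [CA5, C, default, -0.56, 0.946, -0.9753]
- [CA6, C, default, -0.7967, -0.0085, -1.9577]
- [CL1, Cl, Cl_aryl, -1.3245, -0.8007, -4.4921]
- [CL2, Cl, Cl_aryl, -0.8008, -1.6892, -1.5475]
- [N1, N, N_NHR, -0.1163, -1.7954, 2.0159]
- [O1A, O, O_ROR, 2.8514, -0.423, -0.6557]
- [O1B, O, O_ROR, -3.7285, -0.0955, 0.632]
- [O2A, O, O_R2CO, 2.5076, 1.6414, 0.3053]
- [O2B, O, O_R2CO, -2.8465, 1.9108, 1.3316]
- [H1, H, default, 6.1169, 0.3046, -1.0662]
- [H10, H, default, -2.1123, -2.1997, 3.6624]
- [H11, H, default, -3.3092, -1.1719, 2.9003]
- [H12, H, default, -5.357, 0.9864, 1.3445]
- [H13, H, default, -5.6882, -0.1676, 0.0369]
- [H14, H, default, -4.8561, 1.3528, -0.347]
- [H15, H, default, -0.1347, 1.5661, 1.0644]
- [H16, H, default, -0.3711, 3.0449, -0.5346]
- [H17, H, default, -0.7874, 3.7511, -2.8751]
- [H18, H, default, -1.2096, 2.0481, -4.6278]
- [H1N, H, H_NHR, -0.0569, -2.6627, 2.5434]
- [H2, H, default, 5.388, -1.0617, -0.1887]
- [H3, H, default, 5.1425, 0.5793, 0.3948]
- [H4, H, default, 4.1022, -0.5321, -2.2671]
- [H5, H, default, 3.8211, 1.1137, -1.7042]
- [H6, H, default, 2.3675, -2.9588, 1.1133]
- [H7, H, default, 3.2188, -1.4898, 1.6411]
- [H8, H, default, 2.2995, -2.4239, 2.8036]
- [H9, H, default, -2.8493, -2.707, 2.1304]
bonds:
- [C10A, C11A]
- [C10A, H4]
- [C10A, H5]
- [C10A, O1A]
- [C10B, H12]
- [C10B, H13]
- [C10B, H14]
- [C10B, O1B]
- [C11A, H1]
- [C11A, H2]
- [C11A, H3]
- [C2, C3]
- [C2, C7]
- [C2, N1]
- [C3, C4]
- [C3, C9A]
- [C4, C5]
- [C4, CA5]
- [C4, H15]
- [C5, C6]
- [C5, C9B]
- [C6, C8]
- [C6, N1]
- [C7, H6]
- [C7, H7]
- [C7, H8]
- [C8, H10]
- [C8, H11]
- [C8, H9]
- [C9A, O1A]
- [C9A, O2A]
- [C9B, O1B]
- [C9B, O2B]
- [CA1, CA2]
- [CA1, CA6]
- [CA1, CL1]
- [CA2, CA3]
- [CA2, H18]
- [CA3, CA4]
- [CA3, H17]
- [CA4, CA5]
- [CA4, H16]
- [CA5, CA6]
- [CA6, CL2]
- [H1N, N1]
rotatable_groups:
- axis: [C3, C9A]
  moved: [C10A, C11A, H1, H2, H3, H4, H5, O1A, O2A]
- axis: [C5, C9B]
  moved: [C10B, H12, H13, H14, O1B, O2B]
- axis: [C2, C7]
  moved: [H6, H7, H8]
- axis: [C6, C8]
  moved: [H10, H11, H9]
- axis: [C10A, C11A]
  moved: [H1, H2, H3]
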