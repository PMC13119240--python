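name: nifedipine
conformer_id: beta
atoms:
- [C10A, C, C_CH3OR, 4.302, -1.1924, -1.2962]
- [C10B, C, C_CH3OR, -3.947, 2.9732, -0.0631]
- [C2, C, C_pyridine_NIF, 0.0616, -1.4512, -1.8193]
- [C3, C, C_pyridine_NIF, 0.7299, -0.4891, -1.1421]
- [C4, C, C_pyridine_NIF, 0.0117, 0.452, -0.1664]
- [C5, C, C_pyridine_NIF, -1.5048, 0.2926, -0.2172]
- [C6, C, C_pyridine_NIF, -2.0911, -0.7067, -0.9143]
- [C7, C, C_CH3_CH2, 0.6783, -2.3624, -2.8501]
- [C8, C, C_CH3_CH2, -3.5804, -0.9249, -1.0084]
- [C9A, C, C_R2CO, 2.1797, -0.2248, -1.2779]
- [C9B, C, C_R2CO, -2.3311, 1.3562, 0.3892]
- [CA1, C, default, 1.7875, 1.0007, 3.2372]
- [CA2, C, default, 1.6347, -0.2541, 3.8155]
- [CA3, C, default, 0.9561, -1.2563, 3.132]
- [CA4, C, default, 0.4303, -1.0038, 1.8703]
- [CA5, C, default, 0.5832, 0.2509, 1.292]
- [CA6, C, C_CNO2, 1.2618, 1.2532, 1.9755]
- [N1, N, N_NHR, -1.3028, -1.6078, -1.6162]
- [N2, N, N_CNO2, 1.4234, 2.5801, 1.364]
- [O1A, O, O_ROR, 2.8871, -1.381, -1.2579]
- [O1B, O, O_ROR, -3.0867, 1.9504, -0.5644]
- [O2A, O, O_R2CO, 2.6484, 0.9028, -1.301]
- [O2B, O, O_R2CO, -2.2888, 1.6585, 1.5718]
- [O3A, O, O_CNO2, 0.4094, 3.1706, 0.9684]
- [O3B, O, O_CNO2, 2.5613, 3.0661, 1.4157]
- [H1, H, default, 4.7751, -2.1782, -1.2888]
- [H10, H, default, -4.5485, 3.3473, -0.8961]
- [H11, H, default, -4.6234, 2.5714, 0.6981]
- [H12, H, default, -3.3579, 3.8028, 0.34]
- [H13, H, default, 0.2177, 1.4624, -0.535]
- [H14, H, default, -0.1018, -1.7898, 1.3343]
- [H15, H, default, 0.8362, -2.2403, 3.5854]
- [H16, H, default, 2.0469, -0.4521, 4.8049]
- [H17, H, default, 2.3196, 1.7866, 3.7732]
- [H1N, H, H_NHR, -1.7903, -2.2532, -2.2344]
- [H2, H, default, 4.5957, -0.6742, -2.2144]
- [H3, H, default, 4.6384, -0.6399, -0.4132]
- [H4, H, default, 0.9313, -3.3268, -2.3986]
- [H5, H, default, -0.024, -2.545, -3.6715]
- [H6, H, default, 1.5755, -1.937, -3.3087]
- [H7, H, default, -4.1448, -0.386, -0.2425]
- [H8, H, default, -3.9448, -0.6134, -1.9926]
- [H9, H, default, -3.8145, -1.9875, -0.8771]
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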