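name: nifedipine
conformer_id: alpha
atoms:
- [C10A, C, C_CH3OR, 4.1903, -1.1397, -1.5408]
- [C10B, C, C_CH3OR, -2.9331, 2.5033, 2.1426]
- [C2, C, C_pyridine_NIF, -0.0501, -1.3985, -2.0639]
- [C3, C, C_pyridine_NIF, 0.6182, -0.4365, -1.3867]
- [C4, C, C_pyridine_NIF, -0.1, 0.5047, -0.411]
- [C5, C, C_pyridine_NIF, -1.6166, 0.3453, -0.4618]
- [C6, C, C_pyridine_NIF, -2.2028, -0.654, -1.1589]
- [C7, C, C_CH3_CH2, 0.5666, -2.3097, -3.0947]
- [C8, C, C_CH3_CH2, -3.6921, -0.8723, -1.253]
- [C9A, C, C_R2CO, 2.068, -0.1721, -1.5225]
- [C9B, C, C_R2CO, -2.4428, 1.4089, 0.1446]
- [CA1, C, default, 1.6758, 1.0533, 2.9926]
- [CA2, C, default, 1.5229, -0.2014, 3.5709]
- [CA3, C, default, 0.8444, -1.2037, 2.8874]
- [CA4, C, default, 0.3186, -0.9512, 1.6257]
- [CA5, C, default, 0.4715, 0.3036, 1.0474]
- [CA6, C, C_CNO2, 1.15, 1.3058, 1.7309]
- [N1, N, N_NHR, -1.4145, -1.5552, -1.8607]
- [N2, N, N_CNO2, 1.3117, 2.6328, 1.1194]
- [O1A, O, O_ROR, 2.7754, -1.3283, -1.5025]
- [O1B, O, O_ROR, -2.2008, 1.476, 1.4751]
- [O2A, O, O_R2CO, 2.5367, 0.9555, -1.5456]
- [O2B, O, O_R2CO, -3.2453, 2.0853, -0.4802]
- [O3A, O, O_CNO2, 0.2977, 3.2233, 0.7238]
- [O3B, O, O_CNO2, 2.4496, 3.1188, 1.1711]
- [H1, H, default, 4.6634, -2.1255, -1.5334]
- [H10, H, default, -2.6269, 2.5093, 3.1923]
- [H11, H, default, -2.706, 3.4834, 1.7111]
- [H12, H, default, -4.007, 2.2978, 2.0953]
- [H13, H, default, 0.106, 1.5151, -0.7795]
- [H14, H, default, -0.2135, -1.7371, 1.0897]
- [H15, H, default, 0.7245, -2.1876, 3.3408]
- [H16, H, default, 1.9352, -0.3994, 4.5603]
- [H17, H, default, 2.2079, 1.8392, 3.5286]
- [H1N, H, H_NHR, -1.902, -2.2006, -2.479]
- [H2, H, default, 4.484, -0.6215, -2.459]
- [H3, H, default, 4.5267, -0.5872, -0.6578]
- [H4, H, default, 0.8195, -3.2742, -2.6432]
- [H5, H, default, -0.1358, -2.4923, -3.9161]
- [H6, H, default, 1.4638, -1.8843, -3.5533]
- [H7, H, default, -4.2565, -0.3334, -0.4871]
- [H8, H, default, -4.0565, -0.5608, -2.2372]
- [H9, H, default, -3.9262, -1.9348, -1.1217]
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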