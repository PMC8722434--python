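# 32-channel 10/20 montage: electrode order, scalp regions, 2-D unit-disc
# positions (x = right, y = anterior) and the nearest-neighbour adjacency used
# by the Hjorth surface Laplacian. Edit-and-reload to override region or
# neighbour assignments.
name: standard-1020-32
names:
  [Fp1, Fp2, F7, F3, Fz, F4, F8, FC5, FC1, FC2, FC6, A1, T7, T8, A2,
   C3, Cz, C4, CP5, CP1, CP2, CP6, P7, P3, Pz, P4, P8, PO3, PO4, O1, Oz, O2]
regions:
  frontal:   [Fp1, Fp2, F7, F3, Fz, F4, F8, FC5, FC1, FC2, FC6]
  central:   [C3, Cz, C4, CP5, CP1, CP2, CP6]
  temporal:  [T7, T8, A1, A2]
  parietal:  [P7, P3, Pz, P4, P8, PO3, PO4]
  occipital: [O1, Oz, O2]
positions:
  Fp1: [-0.31, 0.95]
  Fp2: [0.31, 0.95]
  F7: [-0.81, 0.59]
  F3: [-0.43, 0.55]
  Fz: [0.0, 0.50]
  F4: [0.43, 0.55]
  F8: [0.81, 0.59]
  FC5: [-0.69, 0.28]
  FC1: [-0.23, 0.26]
  FC2: [0.23, 0.26]
  FC6: [0.69, 0.28]
  A1: [-1.0, 0.0]
  T7: [-0.85, 0.0]
  T8: [0.85, 0.0]
  A2: [1.0, 0.0]
  C3: [-0.45, 0.0]
  Cz: [0.0, 0.0]
  C4: [0.45, 0.0]
  CP5: [-0.69, -0.28]
  CP1: [-0.23, -0.26]
  CP2: [0.23, -0.26]
  CP6: [0.69, -0.28]
  P7: [-0.81, -0.59]
  P3: [-0.43, -0.55]
  Pz: [0.0, -0.50]
  P4: [0.43, -0.55]
  P8: [0.81, -0.59]
  PO3: [-0.35, -0.75]
  PO4: [0.35, -0.75]
  O1: [-0.31, -0.95]
  Oz: [0.0, -0.92]
  O2: [0.31, -0.95]
# Undirected neighbour pairs; symmetry is enforced on load.
adjacency:
  - [Fp1, Fp2]
  - [Fp1, F3]
  - [Fp1, F7]
  - [Fp2, F4]
  - [Fp2, F8]
  - [F7, F3]
  - [F7, FC5]
  - [F7, T7]
  - [F3, Fz]
  - [F3, FC5]
  - [F3, FC1]
  - [Fz, F4]
  - [Fz, FC1]
  - [Fz, FC2]
  - [F4, F8]
  - [F4, FC2]
  - [F4, FC6]
  - [F8, FC6]
  - [F8, T8]
  - [FC5, C3]
  - [FC5, T7]
  - [FC1, Cz]
  - [FC1, C3]
  - [FC2, Cz]
  - [FC2, C4]
  - [FC6, C4]
  - [FC6, T8]
  - [A1, T7]
  - [A1, P7]
  - [T7, C3]
  - [T7, CP5]
  - [T8, C4]
  - [T8, CP6]
  - [A2, T8]
  - [A2, P8]
  - [C3, Cz]
  - [C3, CP5]
  - [C3, CP1]
  - [Cz, C4]
  - [Cz, CP1]
  - [Cz, CP2]
  - [C4, CP2]
  - [C4, CP6]
  - [CP5, P7]
  - [CP5, P3]
  - [CP1, P3]
  - [CP1, Pz]
  - [CP2, Pz]
  - [CP2, P4]
  - [CP6, P4]
  - [CP6, P8]
  - [P7, P3]
  - [P7, O1]
  - [P3, Pz]
  - [P3, PO3]
  - [Pz, P4]
  - [Pz, PO3]
  - [Pz, PO4]
  - [P4, P8]
  - [P4, PO4]
  - [P8, O2]
  - [PO3, O1]
  - [PO3, Oz]
  - [PO4, Oz]
  - [PO4, O2]
  - [O1, Oz]
  - [Oz, O2]
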