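# Default parameter fixture for the anti-CD4/CD70 DuetMab panel.
#
# Numbers are stored in the units of the source table headers:
#   k1, k2                    x1e5   1/(M s)   volume-phase association
#   k_neg1, k_neg2, k_neg4    x1e-3  1/s       dissociation
#   t_half_1, t_half_2               s         monovalent complex half-lives
#   k3                        x1e13  dm^2/(mol s)  surface cross-link association
# t_half_* and k_neg4 are tabulated derived values kept for cross-checking;
# the loader re-derives k_neg3/k_neg4 from the measured constants via the
# microscopic-reversibility closure.
variants:
  parent:
    {k1: 2.8, k_neg1: 0.26, t_half_1: 2665, k_neg4: 0.19, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}
  VkY92A:
    {k1: 2.0, k_neg1: 1.9, t_half_1: 365, k_neg4: 1.9, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}
  VkY91A:
    {k1: 2.8, k_neg1: 4.7, t_half_1: 147, k_neg4: 3.3, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}
  VkR95A:
    {k1: 5.4, k_neg1: 23, t_half_1: 30, k_neg4: 8.5, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}
  VkR95A+VhD97A:
    {k1: 5.6, k_neg1: 35, t_half_1: 20, k_neg4: 12.5, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}
  VkR94A+VhY99A:
    {k1: 5.2, k_neg1: 36, t_half_1: 19, k_neg4: 13.8, k2: 2.0, k_neg2: 4.9, t_half_2: 141, k3: 2.4}

# Receptor copy numbers per cell; geometry and lateral mobility shared by
# all three cell types (10 um diameter sphere, area pi*d^2).
# Diffusion coefficients in cm^2/s: 5e-10 for each membrane target (median
# of published CD4 estimates), 4e-7 for IgG free in solution.
cells:
  dual_positive:
    {n_T1_per_cell: 82000, n_T2_per_cell: 92000, cell_diameter_um: 10.0,
     D_T1_cm2_s: 5.0e-10, D_T2_cm2_s: 5.0e-10, D_antibody_cm2_s: 4.0e-7}
  cd4_only:
    {n_T1_per_cell: 68000, n_T2_per_cell: 0, cell_diameter_um: 10.0,
     D_T1_cm2_s: 5.0e-10, D_T2_cm2_s: 5.0e-10, D_antibody_cm2_s: 4.0e-7}
  cd70_only:
    {n_T1_per_cell: 0, n_T2_per_cell: 55000, cell_diameter_um: 10.0,
     D_T1_cm2_s: 5.0e-10, D_T2_cm2_s: 5.0e-10, D_antibody_cm2_s: 4.0e-7}

assay:
  incubation_time_s: 3600        # 1 h incubation at 4 C
  wash_time_s: 240               # two spin-resuspend cycles + acquisition
  mfi_conversion: 1.18           # bound molecules per MFI unit
  constant_antibody: true
  antibody_concentrations_M:     # default flow-cytometry titration grid
    [1.0e-11, 3.16e-11, 1.0e-10, 3.16e-10, 1.0e-9, 3.16e-9,
     1.0e-8, 3.16e-8, 1.0e-7]
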