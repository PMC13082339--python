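scenario: basal
t0_days: 1.0
t_end_days: 5.5
dt_days: 0.05
output_cadence_days: 0.5
t_phase12: 1.5
t_phase23: 3.2
d_prolif: 4
divisions_off_after_phase1: false
area_threshold_um2: 320.0
apical_angle_deg: 60.0
apical_period_days: 0.35
apical_daughter_frac: 0.3
apical_k_par: 0.75
apical_k_per: 0.4
blade_k_par_phase1: 0.35
blade_k_per_phase1: 0.3
blade_k_par_phase2: 0.9
blade_k_per_phase2: 0.38
k_grad_slope: 0.15
k_grad_floor: 0.25
attach_k: 0.02
midrib_t_onset: 2.0
midrib_max_base_distance: 5
midrib_max_offset_um: 9.0
midrib_k_per_factor: 0.25
diff_elongation_boost: 1.45
diff_tau_e_days: 0.7
diff_tau_d_days: 0.4
material_E_MPa: 100.0
material_nu: 0.3
solver_tol: 0.1
solver_max_iter: 3000
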