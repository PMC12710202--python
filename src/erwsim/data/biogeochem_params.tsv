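parameter	value	units	source
v_lignin	2.0	g C (g enzyme)-1 d-1	default_calibration
k_lignin	300.0	g C m-2	default_calibration
v_cellulose	4.0	g C (g enzyme)-1 d-1	default_calibration
k_cellulose	300.0	g C m-2	default_calibration
v_maoc	0.05	g C (g enzyme)-1 d-1	default_calibration
k_maoc	3000.0	g C m-2	default_calibration
f_maoc_max	0.35	-	default_calibration
k_maoc_half	4000.0	g C m-2	default_calibration
v_doc	0.3	g C (g biomass)-1 d-1	default_calibration
k_doc	20.0	g C m-2	default_calibration
yield_microbe	0.40	-	mend_lineage_default
maint_rate	0.005	d-1	default_calibration
enz_production	0.003	d-1	default_calibration
enz_turnover	0.05	d-1	default_calibration
mortality	0.010	d-1	default_calibration
dead_to_poc	0.30	-	default_calibration
dead_to_doc	0.30	-	default_calibration
dead_to_maoc	0.40	-	default_calibration
myco_resp_frac	0.5	-	default_calibration
myco_maint	0.002	d-1	default_calibration
myco_mortality	0.010	d-1	default_calibration
ew_graze	0.002	d-1	default_calibration
k_ew	800.0	g C m-2	default_calibration
ew_assim	0.35	-	default_calibration
ew_resp_frac	0.60	-	default_calibration
ew_mortality	0.008	d-1	default_calibration
litter_k_ag_leaf	0.008	d-1	century_lineage_default
litter_k_ag_wood	0.0008	d-1	century_lineage_default
litter_k_ag_fine	0.012	d-1	century_lineage_default
litter_k_ag_repro	0.010	d-1	century_lineage_default
litter_k_bg_root	0.006	d-1	century_lineage_default
litter_k_bg_wood	0.0006	d-1	century_lineage_default
litter_k_bg_fine	0.012	d-1	century_lineage_default
litter_k_bg_coarse	0.002	d-1	century_lineage_default
litter_resp_frac	0.45	-	default_calibration
litter_to_lignin	0.30	-	default_calibration
litter_to_cellulose	0.50	-	default_calibration
litter_to_doc	0.20	-	default_calibration
q10	2.0	-	default_calibration
t_ref	20.0	degC	default_calibration
s_opt	0.6	-	default_calibration
ph_opt	6.5	-	default_calibration
ph_sigma	1.5	-	default_calibration
lambda_n	0.6	-	default_calibration
lambda_p	0.6	-	default_calibration
lambda_x	0.6	-	default_calibration
f_org_lea	0.10	-	default_calibration
cn_microbe	8.0	g C (g N)-1	mend_lineage_default
cp_microbe	50.0	g C (g P)-1	mend_lineage_default
k_nitrification	0.05	d-1	default_calibration
k_volatilisation	0.20	d-1	default_calibration
k_denitrification	0.10	d-1	default_calibration
k_fix_p	0.005	d-1	default_calibration
k_pri_p	1.0e-5	d-1	default_calibration
k_fix_cation	1.0e-4	d-1	default_calibration
k_pri_cation	1.0e-5	d-1	default_calibration
k_fix_si	5.0e-4	d-1	default_calibration
k_pri_si	5.0e-6	d-1	default_calibration
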