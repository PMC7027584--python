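trial_id,year,drug_class,drug_names,setting,symptom,instrument,run_in_present,replacement,duration_days,duration_approximate,pct_excluded_after_runin,n_randomized,drug_n,drug_mean_change,drug_sd_change,drug_p_between,drug_ci_low,drug_ci_high,drug_range_width,drug_somnolence,drug_eps,drug_deaths,drug_dropouts,plc_n,plc_mean_change,plc_sd_change,plc_p_between,plc_ci_low,plc_ci_high,plc_range_width,plc_somnolence,plc_eps,plc_deaths,plc_dropouts
Hamilton_1962,1962,conventional,trifluoperazine,hospital,diverse,,no,none,,no,,27,,,,,,,,,,,,,,,,,,,,,,
Sugerman_1964,1964,conventional,haloperidol,hospital,diverse,,no,none,,no,,18,,,,,,,,,,,,,,,,,,,,,,
Rada_1976,1976,conventional,thiothixene,hospital,diverse,,yes,placebo,7,no,0.0,42,,,,,,,,,,,,,,,,,,,,,,
Barnes_1982,1982,conventional,thioridazine;loxapine,nursing_home,diverse,,yes,placebo,14,no,0.117,53,,,,,,,,,,,,,,,,,,,,,,
Petrie_1982,1982,conventional,haloperidol;loxapine,hospital,diverse,,yes,placebo,14,no,0.0,61,,,,,,,,,,,,,,,,,,,,,,
Stotsky_1984,1984,conventional,thioridazine,mixed,diverse,,yes,washout_only,14,no,,358,,,,,,,,,,,,,,,,,,,,,,
Finkel_1995,1995,conventional,thiothixene,nursing_home,agitation,,yes,washout_only,7,no,0.0,33,,,,,,,,,,,,,,,,,,,,,,
Auchus_1997,1997,conventional,haloperidol,outpatients,agitation,,yes,washout_only,14,no,0.0,12,,,,,,,,,,,,,,,,,,,,,,
Devanand_1998,1998,conventional,haloperidol,outpatients,diverse,,yes,placebo,7,no,0.07,66,,,,,,,,,,,,,,,,,,,,,,
Teri_2000,2000,conventional,haloperidol,hospital,agitation,,yes,washout_only,14,no,0.0,70,,,,,,,,,,,,,,,,,,,,,,
Pollock_2002,2002,conventional,perphenazine,nursing_home,diverse,,yes,washout_only,6,yes,,54,,,,,,,,,,,,,,,,,,,,,,
Satterlee_1995,1995,atypical,olanzapine,nursing_home,psychosis,,yes,washout_only,,no,0.177,238,,,,,,,,,,,,,,,,,,,,,,
JanssenPh_1997,1997,atypical,risperidone,not_reported,diverse,,yes,placebo,7,no,,39,,,,,,,,,,,,,,,,,,,,,,
Katz_1999,1999,atypical,risperidone,nursing_home,diverse,,yes,placebo,7,no,0.143,625,,,,,,,,,,,,,,,,,,,,,,
Street_2000,2000,atypical,olanzapine,nursing_home,diverse,,yes,placebo,14,no,0.285,206,,,,,,,,,,,,,,,,,,,,,,
Brodaty_2003,2003,atypical,risperidone,nursing_home,aggression,,yes,placebo,7,no,0.102,345,,,,,,,,,,,,,,,,,,,,,,
JanssenPh_2003,2003,atypical,risperidone,nursing_home,psychosis,,yes,placebo,7,no,,18,,,,,,,,,,,,,,,,,,,,,,
DeDeyn_2004,2004,atypical,olanzapine,nursing_home,psychosis,,yes,placebo,14,no,,652,,,,,,,,,,,,,,,,,,,,,,
Ballard_2005,2005,atypical,quetiapine,nursing_home,agitation,,no,none,,no,,62,,,,,,,,,,,,,,,,,,,,,,
DeDeyn_2005,2005,atypical,aripiprazole,outpatients,psychosis,,yes,washout_only,7,no,,208,,,,,,,,,,,,,,,,,,,,,,
Deberdt_2005,2005,atypical,risperidone;olanzapine,mixed,psychosis,,yes,placebo,14,no,,494,,,,,,,,,,,,,,,,,,,,,,
JanssenPh_2005,2005,atypical,risperidone,not_reported,psychosis,,yes,active_drug,7,no,,33,,,,,,,,,,,,,,,,,,,,,,
Mintzer_2006,2006,atypical,risperidone,nursing_home,psychosis,,yes,placebo,7,no,0.155,473,,,,,,,,,,,,,,,,,,,,,,
Schneider_2006,2006,atypical,risperidone;olanzapine;quetiapine,outpatients,diverse,,no,none,,no,,421,,,,,,,,,,,,,,,,,,,,,,
Mintzer_2007,2007,atypical,aripiprazole,nursing_home,psychosis,,yes,washout_only,7,no,,487,,,,,,,,,,,,,,,,,,,,,,
Zhong_2007,2007,atypical,quetiapine,nursing_home,agitation,,no,none,,no,,333,,,,,,,,,,,,,,,,,,,,,,
Paleacu_2008,2008,atypical,quetiapine,not_reported,diverse,,yes,active_drug,14,no,,40,,,,,,,,,,,,,,,,,,,,,,
Streim_2008,2008,atypical,aripiprazole,nursing_home,psychosis,,yes,washout_only,7,no,,256,,,,,,,,,,,,,,,,,,,,,,
OtsukaPh_2017a,2017,atypical,brexpiprazole,nursing_home,agitation,,yes,washout_only,42,no,,413,,,,,,,,,,,,,,,,,,,,,,
OtsukaPh_2017b,2017,atypical,brexpiprazole,mixed,agitation,,yes,washout_only,42,no,,270,,,,,,,,,,,,,,,,,,,,,,
ACADIA_2018,2018,atypical,pimavanserin,mixed,agitation,,yes,washout_only,28,no,,111,,,,,,,,,,,,,,,,,,,,,,
Ballard_2018,2018,atypical,pimavanserin,nursing_home,psychosis,,yes,washout_only,21,no,0.121,181,,,,,,,,,,,,,,,,,,,,,,
Allain_2000,2000,both,tiapride;haloperidol,mixed,agitation,,no,none,,no,,306,,,,,,,,,,,,,,,,,,,,,,
DeDeyn_1999,1999,both,risperidone;haloperidol,nursing_home,diverse,,yes,placebo,7,no,0.073,344,,,,,,,,,,,,,,,,,,,,,,
Tariot_2006,2006,both,quetiapine;haloperidol,nursing_home,psychosis,,yes,washout_only,2,yes,0.246,284,,,,,,,,,,,,,,,,,,,,,,
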