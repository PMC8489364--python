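# Descending-phase median cardio-respiratory endpoints per PEEP level,
# transcribed from the summary tables of a published porcine experiment
# combining intra-abdominal hypertension (IAP 27 cmH2O) with oleic-acid
# lung injury. One synthetic "median" subject per condition; used as the
# offline worked-example input for the best-PEEP selector.
# Units: pressures cmH2O, elastances cmH2O/L, P/F mmHg, cardiac output
# L/min, gas volume mL, tissue mass g, total lung volume L, fractions %.
subject,condition,phase,peep_cmH2O,endpoint,value
median,healthy,descending,5,pf_ratio,502
median,healthy,descending,12,pf_ratio,532
median,healthy,descending,17,pf_ratio,512
median,healthy,descending,22,pf_ratio,513
median,healthy,descending,27,pf_ratio,515
median,healthy,descending,5,p_aw_insp,31
median,healthy,descending,12,p_aw_insp,37
median,healthy,descending,17,p_aw_insp,41
median,healthy,descending,22,p_aw_insp,43
median,healthy,descending,27,p_aw_insp,51
median,healthy,descending,5,p_es_exp,12
median,healthy,descending,12,p_es_exp,17
median,healthy,descending,17,p_es_exp,21
median,healthy,descending,22,p_es_exp,24
median,healthy,descending,27,p_es_exp,27
median,healthy,descending,5,p_es_insp,29
median,healthy,descending,12,p_es_insp,34
median,healthy,descending,17,p_es_insp,36
median,healthy,descending,22,p_es_insp,38
median,healthy,descending,27,p_es_insp,43
median,healthy,descending,5,elastance_rs,103
median,healthy,descending,12,elastance_rs,94
median,healthy,descending,17,elastance_rs,85
median,healthy,descending,22,elastance_rs,81
median,healthy,descending,27,elastance_rs,92
median,healthy,descending,5,elastance_cw,67
median,healthy,descending,12,elastance_cw,66
median,healthy,descending,17,elastance_cw,53
median,healthy,descending,22,elastance_cw,55
median,healthy,descending,27,elastance_cw,60
median,healthy,descending,5,elastance_lung,35
median,healthy,descending,12,elastance_lung,35
median,healthy,descending,17,elastance_lung,30
median,healthy,descending,22,elastance_lung,27
median,healthy,descending,27,elastance_lung,31
median,healthy,descending,5,cardiac_output,4.4
median,healthy,descending,12,cardiac_output,3.9
median,healthy,descending,17,cardiac_output,3.2
median,healthy,descending,22,cardiac_output,2.9
median,healthy,descending,27,cardiac_output,2.8
median,healthy,descending,5,total_lung_volume,0.8
median,healthy,descending,12,total_lung_volume,0.9
median,healthy,descending,17,total_lung_volume,1.0
median,healthy,descending,22,total_lung_volume,1.1
median,healthy,descending,27,total_lung_volume,1.3
median,healthy,descending,5,gas_volume,378
median,healthy,descending,12,gas_volume,511
median,healthy,descending,17,gas_volume,620
median,healthy,descending,22,gas_volume,761
median,healthy,descending,27,gas_volume,903
median,healthy,descending,5,tissue_mass,338
median,healthy,descending,12,tissue_mass,355
median,healthy,descending,17,tissue_mass,352
median,healthy,descending,22,tissue_mass,353
median,healthy,descending,27,tissue_mass,351
median,healthy,descending,5,overdistended_pct,1
median,healthy,descending,12,overdistended_pct,2
median,healthy,descending,17,overdistended_pct,2
median,healthy,descending,22,overdistended_pct,4
median,healthy,descending,27,overdistended_pct,5
median,healthy,descending,5,normally_aerated_pct,56
median,healthy,descending,12,normally_aerated_pct,68
median,healthy,descending,17,normally_aerated_pct,75
median,healthy,descending,22,normally_aerated_pct,79
median,healthy,descending,27,normally_aerated_pct,82
median,healthy,descending,5,poorly_aerated_pct,32
median,healthy,descending,12,poorly_aerated_pct,23
median,healthy,descending,17,poorly_aerated_pct,18
median,healthy,descending,22,poorly_aerated_pct,14
median,healthy,descending,27,poorly_aerated_pct,9
median,healthy,descending,5,atelectatic_pct,10
median,healthy,descending,12,atelectatic_pct,5
median,healthy,descending,17,atelectatic_pct,3
median,healthy,descending,22,atelectatic_pct,3
median,healthy,descending,27,atelectatic_pct,2
median,injured,descending,5,pf_ratio,175
median,injured,descending,12,pf_ratio,235
median,injured,descending,17,pf_ratio,244
median,injured,descending,22,pf_ratio,285
median,injured,descending,27,pf_ratio,243
median,injured,descending,5,p_aw_insp,38
median,injured,descending,12,p_aw_insp,40
median,injured,descending,17,p_aw_insp,44
median,injured,descending,22,p_aw_insp,47
median,injured,descending,27,p_aw_insp,57
median,injured,descending,5,p_es_exp,30
median,injured,descending,12,p_es_exp,34
median,injured,descending,17,p_es_exp,38
median,injured,descending,22,p_es_exp,40
median,injured,descending,27,p_es_exp,44
median,injured,descending,5,p_es_insp,16
median,injured,descending,12,p_es_insp,20
median,injured,descending,17,p_es_insp,23
median,injured,descending,22,p_es_insp,26
median,injured,descending,27,p_es_insp,29
median,injured,descending,5,elastance_rs,115
median,injured,descending,12,elastance_rs,109
median,injured,descending,17,elastance_rs,101
median,injured,descending,22,elastance_rs,89
median,injured,descending,27,elastance_rs,105
median,injured,descending,5,elastance_cw,62
median,injured,descending,12,elastance_cw,61
median,injured,descending,17,elastance_cw,54
median,injured,descending,22,elastance_cw,53
median,injured,descending,27,elastance_cw,57
median,injured,descending,5,elastance_lung,53
median,injured,descending,12,elastance_lung,42
median,injured,descending,17,elastance_lung,38
median,injured,descending,22,elastance_lung,35
median,injured,descending,27,elastance_lung,48
median,injured,descending,5,cardiac_output,4.2
median,injured,descending,12,cardiac_output,3.3
median,injured,descending,17,cardiac_output,3.2
median,injured,descending,22,cardiac_output,3.1
median,injured,descending,27,cardiac_output,3.3
median,injured,descending,5,total_lung_volume,1.0
median,injured,descending,12,total_lung_volume,1.2
median,injured,descending,17,total_lung_volume,1.3
median,injured,descending,22,total_lung_volume,1.5
median,injured,descending,27,total_lung_volume,1.7
median,injured,descending,5,gas_volume,428
median,injured,descending,12,gas_volume,569
median,injured,descending,17,gas_volume,744
median,injured,descending,22,gas_volume,885
median,injured,descending,27,gas_volume,1024
median,injured,descending,5,tissue_mass,446
median,injured,descending,12,tissue_mass,489
median,injured,descending,17,tissue_mass,526
median,injured,descending,22,tissue_mass,546
median,injured,descending,27,tissue_mass,548
median,injured,descending,5,overdistended_pct,2
median,injured,descending,12,overdistended_pct,2
median,injured,descending,17,overdistended_pct,3
median,injured,descending,22,overdistended_pct,3
median,injured,descending,27,overdistended_pct,5
median,injured,descending,5,normally_aerated_pct,44
median,injured,descending,12,normally_aerated_pct,55
median,injured,descending,17,normally_aerated_pct,60
median,injured,descending,22,normally_aerated_pct,63
median,injured,descending,27,normally_aerated_pct,69
median,injured,descending,5,poorly_aerated_pct,26
median,injured,descending,12,poorly_aerated_pct,25
median,injured,descending,17,poorly_aerated_pct,24
median,injured,descending,22,poorly_aerated_pct,24
median,injured,descending,27,poorly_aerated_pct,19
median,injured,descending,5,atelectatic_pct,26
median,injured,descending,12,atelectatic_pct,18
median,injured,descending,17,atelectatic_pct,11
median,injured,descending,22,atelectatic_pct,6
median,injured,descending,27,atelectatic_pct,3
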