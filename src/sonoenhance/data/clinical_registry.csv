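entry,source,kind,group_a,group_b,mean_a,sd_a,n_a,mean_b,sd_b,n_b,counts_a,counts_b,claim
operation_time_abstract,abstract,t,ultrasound,landmark,7.5,2.07,20,10.2,2.62,20,,,significant
operation_time,results_time_depth,t,ultrasound,landmark,7.7,2.1,20,10.7,2.4,20,,,significant
puncture_depth,results_time_depth,t,ultrasound,landmark,62.5,7.2,20,79.8,8.9,20,,,significant
needle_adjustments,results_adverse_events,t,ultrasound,landmark,2.11,1.31,20,3.25,1.36,20,,,significant
bone_contacts,results_adverse_events,t,ultrasound,landmark,0.68,0.73,20,1.91,1.34,20,,,significant
anesthesia_grades,results_anesthesia_grade,rank,ultrasound,landmark,,,,,,,11/9,13/7,unstated
pain_complaints,results_complications,chisq,landmark,ultrasound,,,,,,,6/14,0/20,significant
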