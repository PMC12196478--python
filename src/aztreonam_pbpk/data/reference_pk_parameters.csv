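# Observed vs model-predicted PK parameters per species study, with the
# relative prediction errors as printed in the reference comparison tables.
# Some printed percentages were computed from unrounded values and cannot be
# recovered exactly from the rounded pairs; the reproduce workflow recomputes
# each row and reports both.
study,parameter,unit,observed,predicted,printed_rpe_pct,printed_are_pct
rat_50mgkg,auc_0_t,ug*h/mL,53.61,55.40,3.4,3.4
rat_50mgkg,auc_0_inf,ug*h/mL,53.62,55.43,3.3,3.3
rat_50mgkg,cl,L/h,0.21,0.216,2.4,2.4
rat_50mgkg,vss,L,0.06,0.068,6.3,6.3
rat_20mgkg,auc_0_t,ug*h/mL,37.69,31.83,-15.5,15.5
rat_20mgkg,auc_0_inf,ug*h/mL,37.93,32.36,-14.7,14.7
rat_20mgkg,cl,L/h,0.122,0.145,18.9,18.9
rat_20mgkg,vss,L,0.074,0.09,21.6,21.6
mouse_20mgkg,auc_0_t,ug*h/mL,30.05,31.26,4.0,4.0
mouse_20mgkg,auc_0_inf,ug*h/mL,30.24,31.54,4.3,4.3
mouse_20mgkg,cl,L/h,0.017,0.016,-3.2,3.2
mouse_20mgkg,vss,L,0.007,0.005,-27.5,27.5
human_500mg,auc_0_t,ug*h/mL,79.78,75.76,-5.0,5.0
human_500mg,auc_0_inf,ug*h/mL,79.97,76.04,-4.9,4.9
human_500mg,cl,L/h,6.16,6.56,6.4,6.4
human_500mg,vss,L,13.190,13.140,-0.4,0.4
dog_25mgkg,auc_0_t,ug*h/mL,37.10,42.96,15.8,15.8
dog_25mgkg,auc_0_inf,ug*h/mL,37.47,43.00,14.8,14.8
dog_25mgkg,cl,L/h,6.338,5.570,-12.1,12.1
dog_25mgkg,vss,L,6.480,4.660,-28.1,28.1
monkey_20mgkg,auc_0_t,ug*h/mL,77.68,84.831,9.2,9.2
monkey_20mgkg,auc_0_inf,ug*h/mL,77.88,84.821,8.9,8.9
monkey_20mgkg,cl,L/h,0.845,0.775,-8.3,8.3
monkey_20mgkg,vss,L,0.835,0.639,-23.5,23.5
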