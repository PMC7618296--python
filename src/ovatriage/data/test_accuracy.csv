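test_id,age_group,threshold_label,sensitivity,sens_ci_low,sens_ci_high,specificity,spec_ci_low,spec_ci_high
CA125_35,UNDER50,35 U/mL,0.753,0.700,0.800,0.925,0.923,0.926
OVATOOLS,UNDER50,1%,0.619,0.561,0.674,0.969,0.968,0.970
OVATOOLS,UNDER50,3%,0.452,0.394,0.510,0.994,0.993,0.994
CA125_35,GE50,35 U/mL,0.865,0.848,0.880,0.943,0.942,0.944
OVATOOLS,GE50,1%,0.911,0.897,0.924,0.891,0.889,0.892
OVATOOLS,GE50,3%,0.831,0.813,0.848,0.965,0.964,0.966
USS,ALL,abnormal,0.85,0.83,0.87,0.83,0.81,0.85
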