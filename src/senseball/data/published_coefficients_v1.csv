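# Published stage-2 coefficient summaries (posterior mean, SD, 95% credible
# interval) for the full OBP, BB% and K% models, version 1.
statistic,coefficient,mean,sd,q2.5,q97.5
OBP,visual_clarity,-0.24,0.17,-0.59,0.10
OBP,contrast_sensitivity,0.13,0.16,-0.18,0.45
OBP,log_depth_perception,0.19,0.16,-0.12,0.50
OBP,near_far_quickness,-0.02,0.15,-0.32,0.28
OBP,target_capture,0.15,0.16,-0.16,0.47
OBP,perception_span,0.64,0.17,0.31,0.99
OBP,eye_hand_coordination,0.22,0.17,-0.11,0.56
OBP,reaction_time,0.21,0.17,-0.11,0.55
OBP,age,0.66,0.17,0.34,1.00
OBP,is_infielder,-0.53,0.31,-1.15,0.08
OBP,is_catcher,-1.28,0.49,-2.25,-0.35
OBP,intercept,-0.13,0.23,-0.57,0.31
BB%,visual_clarity,-0.15,0.10,-0.35,0.05
BB%,contrast_sensitivity,0.04,0.09,-0.14,0.23
BB%,log_depth_perception,0.21,0.10,0.02,0.40
BB%,near_far_quickness,-0.05,0.09,-0.23,0.14
BB%,target_capture,-0.16,0.09,-0.35,0.01
BB%,perception_span,0.15,0.10,-0.04,0.34
BB%,eye_hand_coordination,0.46,0.10,0.26,0.67
BB%,reaction_time,0.23,0.11,0.03,0.44
BB%,age,0.53,0.09,0.36,0.71
BB%,is_infielder,0.05,0.19,-0.33,0.43
BB%,is_catcher,0.15,0.29,-0.40,0.72
BB%,intercept,-0.84,0.14,-1.12,-0.57
K%,visual_clarity,-0.08,0.07,-0.21,0.06
K%,contrast_sensitivity,0.14,0.06,0.02,0.26
K%,log_depth_perception,-0.12,0.07,-0.26,0.02
K%,near_far_quickness,0.21,0.07,0.09,0.34
K%,target_capture,0.16,0.06,0.04,0.29
K%,perception_span,0.34,0.07,0.21,0.47
K%,eye_hand_coordination,-0.19,0.07,-0.32,-0.06
K%,reaction_time,0.12,0.07,-0.02,0.26
K%,age,0.22,0.06,0.09,0.34
K%,is_infielder,0.65,0.13,0.40,0.91
K%,is_catcher,0.26,0.19,-0.12,0.64
K%,intercept,-0.52,0.09,-0.71,-0.34
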