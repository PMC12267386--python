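# Required columns of the per-participant wide summary table.
# Covers every variable of the two descriptive tables: median/mean/ICV and
# error rates per modality and task, kinematic measures for the reach
# tasks, and the choice-minus-simple RT differences.
com_srt_rt_median
com_srt_rt_mean
com_srt_rt_icv
com_srt_omission_rate
com_srt_anticipation_rate
com_crt_rt_median
com_crt_rt_mean
com_crt_rt_icv
com_crt_omission_rate
com_crt_anticipation_rate
com_crt_false_alarm_rate
com_rt_diff_median
com_rt_diff_mean
press_srt_rt_median
press_srt_rt_mean
press_srt_rt_icv
press_srt_omission_rate
press_srt_anticipation_rate
press_crt_rt_median
press_crt_rt_mean
press_crt_rt_icv
press_crt_omission_rate
press_crt_anticipation_rate
press_crt_false_alarm_rate
vr_rt_diff_median
vr_rt_diff_mean
center_rt_median
center_rt_mean
center_rt_icv
center_omission_rate
center_anticipation_rate
center_mt_median
center_mt_mean
center_mt_icv
center_m_omission_rate
center_over_600_rate
center_mv_median
center_mv_mean
center_mv_icv
spatial_rt_median
spatial_rt_mean
spatial_rt_icv
spatial_omission_rate
spatial_anticipation_rate
spatial_mt_median
spatial_mt_mean
spatial_mt_icv
spatial_m_omission_rate
spatial_over_600_rate
spatial_mv_median
spatial_mv_mean
spatial_mv_icv
dynamic_rt_median
dynamic_rt_mean
dynamic_rt_icv
dynamic_omission_rate
dynamic_anticipation_rate
dynamic_mt_median
dynamic_mt_mean
dynamic_mt_icv
dynamic_m_omission_rate
dynamic_over_600_rate
dynamic_mv_median
dynamic_mv_mean
dynamic_mv_icv
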