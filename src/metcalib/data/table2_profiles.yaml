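# Per-activity group distributions (mean/sd) of measured METs, filtered
# synthetic acceleration (mG) and unfiltered/filtered ratio for the ten
# calibration activities of the young-children study cohort.
# NOTE: the coloring MET moments are imputed from group-mean energy
# expenditures (synthetic); see metcalib.simulate.DEFAULT_ACTIVITY_PROFILES.
profiles:
  - {label: watching a video while seated, met_mean: 1.14, met_sd: 0.10, filtered_mean: 7.1, filtered_sd: 4.3, ratio_mean: 2.55, ratio_sd: 0.61, n_subjects: 37, class_truth: non_ambulatory}
  - {label: coloring, met_mean: 1.15, met_sd: 0.17, filtered_mean: 16.3, filtered_sd: 5.9, ratio_mean: 2.57, ratio_sd: 0.45, n_subjects: 33, class_truth: non_ambulatory}
  - {label: playing in a sand box, met_mean: 2.23, met_sd: 0.38, filtered_mean: 102.3, filtered_sd: 20.9, ratio_mean: 2.10, ratio_sd: 0.33, n_subjects: 33, class_truth: non_ambulatory}
  - {label: tidying up, met_mean: 2.46, met_sd: 0.35, filtered_mean: 109.4, filtered_sd: 21.2, ratio_mean: 2.06, ratio_sd: 0.48, n_subjects: 33, class_truth: non_ambulatory}
  - {label: tossing a ball, met_mean: 3.63, met_sd: 0.68, filtered_mean: 283.7, filtered_sd: 70.0, ratio_mean: 1.29, ratio_sd: 0.13, n_subjects: 34, class_truth: non_ambulatory}
  - {label: normal walking, met_mean: 2.10, met_sd: 0.22, filtered_mean: 306.1, filtered_sd: 48.5, ratio_mean: 1.00, ratio_sd: 0.01, n_subjects: 34, class_truth: ambulatory}
  - {label: brisk walking, met_mean: 2.36, met_sd: 0.27, filtered_mean: 373.1, filtered_sd: 47.5, ratio_mean: 1.00, ratio_sd: 0.01, n_subjects: 31, class_truth: ambulatory}
  - {label: jogging, met_mean: 4.16, met_sd: 0.53, filtered_mean: 838.9, filtered_sd: 83.3, ratio_mean: 1.02, ratio_sd: 0.01, n_subjects: 35, class_truth: ambulatory}
  - {label: ascending stairs, met_mean: 4.03, met_sd: 0.49, filtered_mean: 251.7, filtered_sd: 49.3, ratio_mean: 1.12, ratio_sd: 0.24, n_subjects: 32, class_truth: ambulatory}
  - {label: descending stairs, met_mean: 2.00, met_sd: 0.31, filtered_mean: 301.4, filtered_sd: 58.6, ratio_mean: 1.05, ratio_sd: 0.02, n_subjects: 34, class_truth: ambulatory}
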