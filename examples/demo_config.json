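{
 "seed": 7,
 "n_mice_female": 5,
 "n_mice_male": 5,
 "n_nmr_female": 5,
 "n_nmr_male": 5,
 "ecg_duration_s": 30.0,
 "ecg_noise_sd_mv": 0.02,
 "ecg_fs_hz": 2000.0,
 "rr_low": 0.7,
 "rr_high": 1.3,
 "rr_window": 11,
 "n_avg": 100,
 "lead": "L1",
 "selection_alpha": 0.05,
 "doppler_duration_s": 4.0,
 "mouse_age_bins": [0.0, 1.0, 1.7, 2.2, 3.0],
 "nmr_age_bins": [0.0, 10.0, 20.0, 35.0],
 "trend_outcomes": ["qrs_ms", "pr_ms", "hr_bpm", "ef_pct", "ea_ratio"],
 "log_level": "INFO"
}
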