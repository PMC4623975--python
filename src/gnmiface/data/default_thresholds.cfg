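# Default decision thresholds, one block per size regime.
# Calibrated on the synthetic two-class attribute generator
# (sample_attribute_vectors, n=200/class, seed=20150); both regimes
# therefore share values. For real data, calibrate on a labeled
# manifest with `gnmiface calibrate` and pass the file explicitly.
[large]
a_all = 0.040594956053985304
n_all = -0.23497666710573484
p_all = 0.25516387634528365
a_slow = 0.037472795906953515
n_slow = -0.310000389311142
p_slow = 0.2850021143999164
ar = 0.08138345052625612
small_subunit_cutoff = 65

[small]
a_all = 0.040594956053985304
n_all = -0.23497666710573484
p_all = 0.25516387634528365
a_slow = 0.037472795906953515
n_slow = -0.310000389311142
p_slow = 0.2850021143999164
ar = 0.08138345052625612
small_subunit_cutoff = 65

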