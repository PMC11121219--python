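# Default pipeline settings: decimation to 151 points, Kennard-Stone 20/10
# partition on the reference attributes, C grid spanning the useful range,
# SNV + first derivative for breed discrimination.
treatments: [SM, DV1, DV2, NORM-DV1, MSC-SM, MSC-DV1, SNV-SM, ALS-SM, SNV-DV1]
discrimination_treatment: SNV-DV1
decimation_step: 10
n_train: 20
n_test: 10
feature_space: reference
C_grid: [1, 10, 30, 100]
svc_C: 1.0
epsilon: 0.1
r2_train_min: 0.95
slope_train_min: 0.95
r2_test_min: 0.90
targets: ["pH", "L*", "a*", "b*", "protein", "IMF", "C14:0", "C16:0", "C18:0", "C18:1n-9"]
seed: 42
out_dir: results
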