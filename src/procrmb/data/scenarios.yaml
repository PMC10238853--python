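# Benchmark scenarios: true per-dose DLT probabilities for the two-level
# whole-pelvis radiotherapy design (level 1 = 15 fractions, level 2 = 10
# fractions), clinician-reported (C-DLT) and patient-reported (P-DLT).
scenarios:
  - name: "1"    # both levels safe; level 2 is the MTD for both endpoints
    true_c_dlt: [0.05, 0.15]
    true_p_dlt: [0.18, 0.35]
  - name: "2"    # level 2 too toxic for clinicians; level 1 is the MTD
    true_c_dlt: [0.20, 0.40]
    true_p_dlt: [0.18, 0.35]
  - name: "3"    # level 2 exactly at both targets
    true_c_dlt: [0.10, 0.20]
    true_p_dlt: [0.35, 0.55]
  - name: "4"    # level 2 exceeds the patient target; level 1 is the MTD
    true_c_dlt: [0.08, 0.15]
    true_p_dlt: [0.50, 0.65]
  - name: "5"    # both levels exceed the patient target; stop early
    true_c_dlt: [0.08, 0.15]
    true_p_dlt: [0.65, 0.75]
  - name: "6"    # both levels exceed the clinician target; stop early
    true_c_dlt: [0.40, 0.45]
    true_p_dlt: [0.25, 0.35]
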