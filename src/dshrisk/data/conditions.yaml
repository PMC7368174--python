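# Default condition definitions: type 2 diabetes and its comorbidities.
#
# Diagnosis codes are illustrative ICD-9 / ICD-10-CM strings; real deployments
# supply their own curated code sets.  Lab criteria are OR-combined: a single
# encounter meeting any criterion (or carrying a matching diagnosis code)
# indicates the condition.  Control criteria are AND-combined reference
# ranges evaluated on the most recent measurement.

measurements:
  # canonical unit per measurement name; event rows must match (or omit) it
  hba1c: "%"
  fasting_glucose: mg/dL
  random_glucose: mg/dL
  sbp: mmHg
  dbp: mmHg
  ldl: mg/dL
  bmi: kg/m2

conditions:
  t2d:
    diagnosis_codes: ["E11.9", "E11.65", "250.00", "250.02"]
    lab_criteria:
      - {measurement: fasting_glucose, comparator: ">=", threshold: 126.0}
      - {measurement: random_glucose, comparator: ">=", threshold: 200.0}
      - {measurement: hba1c, comparator: ">=", threshold: 6.5}
    control_criteria:
      - {measurement: hba1c, lower: 0.0, upper: 6.5}
    therapy_lines:
      metformin: first
      sulfonylurea: second
      dpp4: second
      glp1: second
      sglt2: second
      meglitinide: second
      insulin: last
      amylin: last

  hypertension:
    diagnosis_codes: ["I10", "401.1", "401.9"]
    lab_criteria:
      - {measurement: sbp, comparator: ">=", threshold: 140.0}
      - {measurement: dbp, comparator: ">=", threshold: 90.0}
    control_criteria:
      - {measurement: sbp, lower: 0.0, upper: 140.0}
      - {measurement: dbp, lower: 0.0, upper: 90.0}
    therapy_lines:
      ace_inhibitor: first
      arb: first
      ccb: first
      diuretic: first
      beta_blocker: second
      alpha_blocker: second
      vasodilator: second
      renin_inhibitor: second
    # three or more concurrent antihypertensive classes counts as last-line
    last_if_n_classes: 3

  hyperlipidemia:
    diagnosis_codes: ["E78.5", "272.4"]
    lab_criteria:
      - {measurement: ldl, comparator: ">=", threshold: 100.0}
    control_criteria:
      - {measurement: ldl, lower: 0.0, upper: 100.0}
    therapy_lines:
      statin: first
      fibrate: second
      absorption_inhibitor: second

  obesity:
    # severity graded by BMI bands rather than pharmacotherapy; "control"
    # is a non-increasing BMI trend
    severity_mode: bands
    diagnosis_codes: ["E66.9", "278.00"]
    lab_criteria:
      - {measurement: bmi, comparator: ">=", threshold: 30.0}
    control_criteria:
      - {measurement: bmi, lower: 0.0, upper: 30.0}
    band_measurement: bmi
    band_thresholds: [35.0, 40.0]
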