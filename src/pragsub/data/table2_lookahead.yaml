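# Default interpretable-covariate coding for the Look AHEAD-like roster.
# Continuous clinical measurements are cut at guideline thresholds; scales
# without a practical decision meaning are removed. Intervals are
# left-closed / right-open on the listed cutpoints.
#
# Note: the fasting-glucose groups (< 54, 54-69.9, >= 70) are transcribed
# verbatim from the source coding table even though the thresholds look
# clinically unusual.
unlisted_policy: keep
rules:
  age:
    action: categorize
    cutpoints: [60]
    labels: ["< 60", "≥ 60"]
  bmi:
    action: categorize
    cutpoints: [18.5, 25, 30, 35, 40]
    labels: ["< 18.5", "18.5–24.9", "25–29.9", "30–34.9", "35–39.9", "≥ 40"]
  alcohol_oz_week:
    action: categorize
    cutpoints: [0.01]
    labels: ["do not drink alcohol", "drink alcohol"]
  fasting_glucose:
    action: categorize
    cutpoints: [54, 70]
    labels: ["< 54", "54–69.9", "≥ 70"]
  hba1c:
    action: categorize
    cutpoints: [5.7, 6.4, 7.0, 8.0, 9.0, 10.0]
    labels: ["< 5.7", "5.7–6.3", "6.4–6.9", "7.0–7.9", "8.0–8.9", "9.0–9.9", "≥ 10"]
  hdl_cholesterol:
    action: categorize
    cutpoints: [40, 60]
    labels: ["< 40", "40–59.9", "≥ 60"]
  ldl_cholesterol:
    action: categorize
    cutpoints: [100, 130, 160, 190]
    labels: ["< 100", "100–129.9", "130–159.9", "160–189.9", "≥ 190"]
  triglycerides:
    action: categorize
    cutpoints: [150, 200, 500]
    labels: ["< 150", "150–199.9", "200–499.9", "≥ 500"]
  urine_albumin:
    action: remove
  urine_creatinine:
    action: remove
  urine_acr:
    action: categorize
    cutpoints: [30, 300]
    labels: ["< 30", "30–299", "≥ 300"]
  systolic_bp:
    action: categorize
    cutpoints: [120, 130, 140, 160, 180]
    labels: ["< 120", "120–129.9", "130–139.9", "140–159.9", "160–179.9", "≥ 180"]
  sf36_general_health:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_mental_health:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_bodily_pain:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_physical_functioning:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_role_emotional:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_role_physical:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_social_functioning:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_vitality:
    action: categorize
    cutpoints: [50]
    labels: ["< 50", "≥ 50"]
  sf36_transition:
    action: remove
  sf36_mcs:
    action: remove
  sf36_pcs:
    action: remove
  beck_score:
    action: categorize
    cutpoints: [10, 20, 30]
    labels: ["< 10", "10–19", "20–29", "≥ 30"]
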