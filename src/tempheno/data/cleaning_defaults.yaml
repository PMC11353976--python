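# Default plausible-value ranges for common outpatient labs and vitals.
# Values outside [min, max] are treated as entry errors and dropped.
# Temperature variables listed under temperature_variables are normalised to
# Fahrenheit (readings below 50 are assumed Celsius).
ranges:
  heart_rate: [20, 300]
  systolic_bp: [40, 300]
  diastolic_bp: [20, 200]
  respiratory_rate: [4, 80]
  temperature: [90, 110]
  bmi: [10, 100]
  glucose: [10, 2000]
  creatinine: [0.1, 30]
  urea_nitrogen: [1, 250]
  sodium: [100, 180]
  potassium: [1, 12]
  chloride: [60, 140]
  hemoglobin: [2, 25]
  hematocrit: [10, 70]
  platelet_count: [1, 2000]
  wbc: [0.1, 200]
temperature_variables:
  - temperature
missingness_cutoff: 0.60
prevalence_cutoff: 0.01
recency_window: 183
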