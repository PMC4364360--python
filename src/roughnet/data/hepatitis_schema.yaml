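# Schema for the UCI hepatitis dataset (155 records, 19 conditions + class).
# Numeric attributes carry the binned domain edges; labels keep their spelling.
# The data itself is not bundled: download it from the UCI repository.
- name: Age
  kind: numeric
  role: condition
  cut_points: ["10", "20", "30", "40", "50", "60", "70", "80"]
- name: Sex
  kind: categorical
  role: condition
- name: Steroid
  kind: categorical
  role: condition
- name: Antivirals
  kind: categorical
  role: condition
- name: Fatigue
  kind: categorical
  role: condition
- name: Malaise
  kind: categorical
  role: condition
- name: Anorexia
  kind: categorical
  role: condition
- name: Liver big
  kind: categorical
  role: condition
- name: Liver firm
  kind: categorical
  role: condition
- name: Spleen palpable
  kind: categorical
  role: condition
- name: Spiders
  kind: categorical
  role: condition
- name: Ascites
  kind: categorical
  role: condition
- name: Varices
  kind: categorical
  role: condition
- name: Bilirubin
  kind: numeric
  role: condition
  cut_points: ["0.39", "0.80", "1.20", "2.00", "3.00", "4.00"]
- name: Alk phosphate
  kind: numeric
  role: condition
  cut_points: ["33", "80", "120", "160", "200", "250"]
- name: Sgot
  kind: numeric
  role: condition
  cut_points: ["13", "100", "200", "300", "400", "500"]
- name: Albumin
  kind: numeric
  role: condition
  cut_points: ["2.1", "3.0", "3.8", "4.5", "5.0", "6.0"]
- name: Protime
  kind: numeric
  role: condition
  cut_points: ["10", "20", "30", "40", "50", "60", "70", "80", "90"]
- name: Histology
  kind: categorical
  role: condition
- name: Class
  kind: categorical
  role: decision
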