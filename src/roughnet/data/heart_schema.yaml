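# Schema for the UCI Statlog heart disease dataset (270 records, 13 features).
# The source publishes ranges, not bins, for the continuous attributes; the
# cut points below are this package's defaults (round clinical breakpoints).
# Data not bundled: download from UCI.
- name: age
  kind: numeric
  role: condition
  cut_points: ["29", "40", "50", "60", "70"]
- name: sex
  kind: categorical
  role: condition
- name: Chp
  kind: categorical
  role: condition
- name: Bp
  kind: numeric
  role: condition
  cut_points: ["94", "120", "140", "160", "180"]
- name: Sch
  kind: numeric
  role: condition
  cut_points: ["126", "200", "240", "280", "320"]
- name: Fbs
  kind: categorical
  role: condition
- name: Ecg
  kind: categorical
  role: condition
- name: Mhrt
  kind: numeric
  role: condition
  cut_points: ["71", "100", "120", "140", "160", "180"]
- name: Exian
  kind: categorical
  role: condition
- name: Opk
  kind: numeric
  role: condition
  cut_points: ["0", "1", "2", "3", "4", "5"]
- name: slope
  kind: categorical
  role: condition
- name: vessel
  kind: categorical
  role: condition
- name: Thal
  kind: categorical
  role: condition
- name: Class
  kind: categorical
  role: decision
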