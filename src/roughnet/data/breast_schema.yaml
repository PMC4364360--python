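# Schema for the UCI Wisconsin breast cancer dataset (699 records after the
# sample-code column is removed). All features are ordinal codes 1-10 and are
# treated as categorical symbols. Data not bundled: download from UCI.
- name: Clump thickness
  kind: categorical
  role: condition
- name: Uniformity of cell size
  kind: categorical
  role: condition
- name: Uniformity of cell shape
  kind: categorical
  role: condition
- name: Marginal adhesion
  kind: categorical
  role: condition
- name: Single epithelial cell size
  kind: categorical
  role: condition
- name: Bare nuclei
  kind: categorical
  role: condition
- name: Bland chromatin
  kind: categorical
  role: condition
- name: Normal nucleoli
  kind: categorical
  role: condition
- name: Mitoses
  kind: categorical
  role: condition
- name: Class
  kind: categorical
  role: decision
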