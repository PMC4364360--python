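# Six-object heart-disease sample: three categorical conditions, binary class.
- name: Chp
  kind: categorical
  role: condition
- name: ECG
  kind: categorical
  role: condition
- name: Vessel
  kind: categorical
  role: condition
- name: Class
  kind: categorical
  role: decision
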