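Chp,ECG,Vessel,Class
2,0,3,Yes
1,2,1,No
3,2,3,Yes
2,0,0,No
3,0,0,No
3,0,0,Yes
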