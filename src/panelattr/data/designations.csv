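specialty_code,designation
01,PCP
08,PCP
11,PCP
38,PCP
06,SCP
13,SCP
20,SCP
29,SCP
66,SCP
83,SCP
90,SCP
50,APP
89,APP
97,APP
35,OTHER
41,OTHER
65,OTHER
70,OTHER
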