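subject,accuracy_training,accuracy_testing,precision,recall,f1
01,70.0,80.0,71.4,100,83.3
02,100,90.0,100,80.0,88.9
03,100,70.0,62.5,100,76.9
04,100,80.0,100,60.0,75.0
05,100,90.0,100,80.0,88.9
06,100,90.0,100,80.0,88.9
07,90.0,50.0,50.0,40.0,44.4
08,100,70.0,62.5,100,76.9
09,100,70.0,100,40.0,57.1
10,100,80.0,100,60.0,75.0
11,80.0,80.0,80.0,80.0,80.0
12,100,90.0,83.3,100,90.9
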