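subject,accuracy_training,accuracy_testing,precision,recall,f1
01,90.00,100.00,100.00,100.00,100.00
02,100.00,60.00,66.67,40.00,50.00
03,100.00,70.00,100.00,40.00,57.14
04,100.00,100.00,100.00,100.00,100.00
05,100.00,70.00,75.00,60.00,66.67
06,100.00,80.00,100.00,60.00,75.00
07,100.00,90.00,100.00,80.00,88.89
08,100.00,80.00,80.00,80.00,80.00
09,100.00,90.00,100.00,80.00,88.89
10,80.00,70.00,100.00,40.00,57.14
11,70.00,50.00,50.00,100.00,66.67
12,90.00,60.00,55.56,100.00,71.43
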