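control_id,sex,age,alps_right,alps_left,matched_patient_ids
1,male,33,1.51,1.52,27
2,male,24,1.52,1.31,1
3,female,57,1.38,1.39,12;16;28;29
4,male,59,1.31,1.31,21;23
5,male,41,1.45,1.47,7
6,male,70,0.90,0.85,13;20;30
7,female,67,1.37,1.46,4;15;17
8,male,49,1.23,1.14,5
9,female,71,1.42,1.25,2;3
10,female,61,0.88,0.93,22
11,male,43,1.51,1.42,18
12,male,52,0.99,1.09,9;10;11;25
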