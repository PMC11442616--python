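patient_id,age,sex,alps_ipsi,alps_contra,tumor_adc,event,tumor_type,tumor_details,tumor_location,tumor_side,ptbe,roi_in_ptbe,included
1,24,male,1.10,1.37,1601,local_recurrence,primary,Diffuse astrocytoma,Left frontal,left,no,False,True
2,73,female,0.98,1.18,525.5,distance_recurrence,metastasis,B-cell lymphoma,Left high frontal,left,no,False,True
3,71,female,0.97,0.98,75.5,distance_recurrence,metastasis,Bronchial carcinoma,Left high frontal,left,yes,True,True
4,68,female,1.12,1.31,810,distance_recurrence,metastasis,Mammary carcinoma,Left occipital,left,yes,False,True
5,48,male,1.14,1.15,1220,first_diagnosis,primary,Unclear,Left temperofronto-parieto insular,left,yes,True,True
6,56,female,,,912,distance_recurrence,metastasis,Mammary carcinoma,Intraventricular,intraventricular,yes,False,False
7,38,male,0.96,1.30,1287,local_recurrence,primary,Glioblastoma,Left frontal,left,yes,True,True
8,59,male,,,1182,local_recurrence,primary,Glioblastoma,Left frontal,left,yes,False,False
9,53,male,1.67,1.81,1558,first_diagnosis,primary,Diffuse astrocytoma,Left temporoinsular,left,yes,False,True
10,51,male,1.39,1.51,1333,local_recurrence,primary,Diffuse astrocytoma,Right frontotemporoinsular,right,no,False,True
11,51,male,1.34,1.58,1291,local_recurrence,primary,Diffuse astrocytoma,Right frontotemporoinsular,right,no,False,True
12,56,female,2.03,2.28,1719,first_diagnosis,primary,Convexity meningioma,Left convexity,left,no,False,True
13,71,male,1.29,1.30,1845,local_recurrence,primary,Glioblastoma,Left temporal,left,yes,False,True
14,72,female,,,2927,distance_recurrence,metastasis,Endometrial adenocarcinoma,Right frontoparietal,right,yes,False,False
15,67,female,1.54,1.44,2688,distance_recurrence,metastasis,Clear cell renal carcinoma,Left temporal,left,yes,False,True
16,60,female,1.13,1.59,2734,local_recurrence,primary,Multifocal glioblastoma,Left parietooccipital and left occipital,left,yes,False,True
17,67,female,1.35,1.35,2883,distance_recurrence,metastasis,Renal cell carcinoma,Left parietooccipital,left,yes,False,True
18,43,male,1.28,1.62,1769,distance_recurrence,metastasis,Bronchial carcinoma,Left temporal,left,yes,False,True
19,62,female,,,824,first_diagnosis,primary,Glial tumor,Left frontoparietal,left,yes,False,False
20,70,male,1.42,1.58,1556,first_diagnosis,primary,Glioblastoma,Right high frontal,right,yes,False,True
21,58,male,1.20,1.22,1140,first_diagnosis,primary,Glioblastoma,Left temporal,left,yes,False,True
22,61,female,1.01,1.19,1798,local_recurrence,primary,Multifocal glioblastoma,Left parietooccipital and left occipital,left,yes,False,True
23,57,male,1.18,1.32,2057,local_recurrence,primary,Glioblastoma,Left temporoinsular,left,yes,True,True
24,61,female,,,1012,first_diagnosis,primary,Glioblastoma,Left temporoparietal,left,yes,False,False
25,50,male,1.34,1.55,2257,local_recurrence,primary,Oligodendroglioma grade III,Left parietal,left,yes,False,True
26,54,male,,,711,first_diagnosis,primary,Glioblastoma,Right frontoparietal,right,yes,False,False
27,32,male,1.30,1.40,1576,first_diagnosis,primary,Oligodendroglioma grade II,Left frontal,left,yes,False,True
28,58,female,1.16,1.17,1059.5,distance_recurrence,metastasis,Bronchial carcinoma,Left parietal and left occipital,left,yes,False,True
29,59,female,1.24,1.89,1628,local_recurrence,primary,Glioblastoma,Left temporoparieto-occipital,left,yes,True,True
30,72,male,1.03,1.25,2444,first_diagnosis,primary,Glioblastoma,Left temporal,left,yes,False,True
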