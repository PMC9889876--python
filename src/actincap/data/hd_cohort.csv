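sample_id,group,age_years,sex,cag_repeats,cap_score_reference,severity_reference
GM02165,HD,57,M,46,140.5239,Severe
GM05031,HD,60,M,45,138.6749,Severe
GM04476,HD,57,M,45,131.7411,Severe
GM04200,HD,53,M,46,130.6626,Severe
GM00305,HD,56,F,45,129.4299,Severe
GM04285,HD,40,M,51,129.4299,Severe
GM06274,HD,56,F,45,129.4299,Severe
GM04807,HD,41,M,50,126.3482,Severe
GM04287,HD,43,M,49,125.886,Severe
GM02147,HD,55,M,44,118.6441,Severe
GM04691,HD,31,M,54,114.6379,Severe
GM04687,HD,37,F,50,114.0216,Severe
GM04709,HD,38,F,49,111.2481,Mild
GM04715,HD,40,M,48,110.9399,Mild
GM04887,HD,48,F,45,110.9399,Mild
GM04196,HD,51,F,44,110.0154,Mild
GM04767,HD,43,F,46,106.0092,Mild
GM04849,HD,28,F,54,103.5439,Mild
GM04212,HD,50,F,43,100.1541,Mild
GM04819,HD,48,M,43,96.14792,Mild
GM04799,HD,47,M,43,94.14484,Mild
GM04721,HD,37,F,46,91.21726,Mild
GM04719,HD,39,F,44,84.12943,Premanifest
GM04847,HD,31,M,46,76.42527,Premanifest
GM04693,HD,33,M,45,76.27119,Premanifest
GM04717,HD,44,F,41,74.57627,Premanifest
GM04689,HD,30,F,45,69.33744,Premanifest
GM04837,HD,23,M,47,60.24653,Premanifest
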