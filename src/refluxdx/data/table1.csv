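questionnaire,questions,answers,entries,data_amount
QoLRAD1,12,84,4276,48917
QoLRAD2,25,175,1723,38800
GERD Question Form 1,57,238,653,33942
GERD Question Form 2,66,353,5041,189765
GERD Question Form 3,81,444,1873,185774
SF-36,11,149,5399,119252
Otolaryngology Form,20,115,1446,21196
Otolaryngology Score,9,28,1602,10603
GERD Postoperative Symptoms Question Form,22,96,156,2922
RDQ,2,72,82,906
Eckardt Score,5,17,10,50
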