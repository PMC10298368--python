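label,axis,group,count
type I achalasia,sex,male,7
type I achalasia,sex,female,7
type I achalasia,age,10-39,5
type I achalasia,age,40-90,9
type II achalasia,sex,male,10
type II achalasia,sex,female,21
type II achalasia,age,10-39,10
type II achalasia,age,40-90,21
type III achalasia,sex,male,4
type III achalasia,sex,female,4
type III achalasia,age,10-39,1
type III achalasia,age,40-90,7
EGJ outflow obstruction,sex,male,1
EGJ outflow obstruction,sex,female,0
EGJ outflow obstruction,age,10-39,0
EGJ outflow obstruction,age,40-90,1
absent contractility,sex,male,4
absent contractility,sex,female,4
absent contractility,age,10-39,2
absent contractility,age,40-90,6
distal esophageal spasm,sex,male,1
distal esophageal spasm,sex,female,0
distal esophageal spasm,age,10-39,0
distal esophageal spasm,age,40-90,1
hypercontractile esophagus (jackhammer),sex,male,5
hypercontractile esophagus (jackhammer),sex,female,4
hypercontractile esophagus (jackhammer),age,10-39,0
hypercontractile esophagus (jackhammer),age,40-90,9
ineffective esophageal motility,sex,male,37
ineffective esophageal motility,sex,female,23
ineffective esophageal motility,age,10-39,29
ineffective esophageal motility,age,40-90,31
fragmented peristalsis,sex,male,1
fragmented peristalsis,sex,female,0
fragmented peristalsis,age,10-39,0
fragmented peristalsis,age,40-90,1
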