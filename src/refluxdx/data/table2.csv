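label,axis,group,count
erosive esophagitis,sex,male,641
erosive esophagitis,sex,female,590
erosive esophagitis,age,10-19,18
erosive esophagitis,age,20-29,119
erosive esophagitis,age,30-39,271
erosive esophagitis,age,40-49,298
erosive esophagitis,age,50-59,299
erosive esophagitis,age,60-69,169
erosive esophagitis,age,70-90,57
reflux hypersensitivity,sex,male,12
reflux hypersensitivity,sex,female,49
reflux hypersensitivity,age,10-19,4
reflux hypersensitivity,age,20-29,8
reflux hypersensitivity,age,30-39,19
reflux hypersensitivity,age,40-49,13
reflux hypersensitivity,age,50-59,13
reflux hypersensitivity,age,60-69,3
reflux hypersensitivity,age,70-90,1
functional heartburn,sex,male,48
functional heartburn,sex,female,121
functional heartburn,age,10-19,2
functional heartburn,age,20-29,18
functional heartburn,age,30-39,42
functional heartburn,age,40-49,49
functional heartburn,age,50-59,37
functional heartburn,age,60-69,19
functional heartburn,age,70-90,2
non-erosive reflux disease,sex,male,307
non-erosive reflux disease,sex,female,284
non-erosive reflux disease,age,10-19,10
non-erosive reflux disease,age,20-29,60
non-erosive reflux disease,age,30-39,127
non-erosive reflux disease,age,40-49,149
non-erosive reflux disease,age,50-59,144
non-erosive reflux disease,age,60-69,77
non-erosive reflux disease,age,70-90,24
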