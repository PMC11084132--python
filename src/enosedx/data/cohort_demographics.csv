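table,group,category,count
training_sex,lung_cancer,male,39
training_sex,lung_cancer,female,31
training_sex,control,male,19
training_sex,control,female,29
validation_sex,lung_cancer,male,8
validation_sex,lung_cancer,female,12
validation_sex,control,male,18
validation_sex,control,female,12
test_sex,lung_cancer,male,18
test_sex,lung_cancer,female,10
test_sex,control,male,15
test_sex,control,female,20
training_smoking,lung_cancer,current,7
training_smoking,lung_cancer,ex,20
training_smoking,lung_cancer,never,43
training_smoking,control,current,8
training_smoking,control,ex,3
training_smoking,control,never,37
validation_smoking,lung_cancer,current,1
validation_smoking,lung_cancer,ex,6
validation_smoking,lung_cancer,never,13
validation_smoking,control,current,4
validation_smoking,control,ex,4
validation_smoking,control,never,22
test_smoking,lung_cancer,current,7
test_smoking,lung_cancer,ex,8
test_smoking,lung_cancer,never,13
test_smoking,control,current,6
test_smoking,control,ex,6
test_smoking,control,never,23
training_DM,lung_cancer,yes,8
training_DM,lung_cancer,no,62
training_DM,control,yes,5
training_DM,control,no,43
validation_DM,lung_cancer,yes,3
validation_DM,lung_cancer,no,17
validation_DM,control,yes,4
validation_DM,control,no,26
test_DM,lung_cancer,yes,6
test_DM,lung_cancer,no,22
test_DM,control,yes,4
test_DM,control,no,31
training_HTN,lung_cancer,yes,24
training_HTN,lung_cancer,no,46
training_HTN,control,yes,13
training_HTN,control,no,35
validation_HTN,lung_cancer,yes,7
validation_HTN,lung_cancer,no,13
validation_HTN,control,yes,7
validation_HTN,control,no,23
test_HTN,lung_cancer,yes,5
test_HTN,lung_cancer,no,23
test_HTN,control,yes,5
test_HTN,control,no,30
training_COPD,lung_cancer,yes,8
training_COPD,lung_cancer,no,62
training_COPD,control,yes,5
training_COPD,control,no,43
validation_COPD,lung_cancer,yes,2
validation_COPD,lung_cancer,no,18
validation_COPD,control,yes,10
validation_COPD,control,no,20
test_COPD,lung_cancer,yes,7
test_COPD,lung_cancer,no,21
test_COPD,control,yes,9
test_COPD,control,no,26
train_vs_validation_sex,training,male,58
train_vs_validation_sex,training,female,60
train_vs_validation_sex,validation,male,26
train_vs_validation_sex,validation,female,24
train_vs_validation_smoking,training,current,15
train_vs_validation_smoking,training,ex,23
train_vs_validation_smoking,training,never,80
train_vs_validation_smoking,validation,current,5
train_vs_validation_smoking,validation,ex,10
train_vs_validation_smoking,validation,never,35
train_vs_validation_DM,training,yes,13
train_vs_validation_DM,training,no,105
train_vs_validation_DM,validation,yes,7
train_vs_validation_DM,validation,no,43
train_vs_validation_HTN,training,yes,37
train_vs_validation_HTN,training,no,81
train_vs_validation_HTN,validation,yes,14
train_vs_validation_HTN,validation,no,36
train_vs_validation_COPD,training,yes,13
train_vs_validation_COPD,training,no,105
train_vs_validation_COPD,validation,yes,12
train_vs_validation_COPD,validation,no,38
train_vs_validation_cancer,training,yes,71
train_vs_validation_cancer,training,no,47
train_vs_validation_cancer,validation,yes,20
train_vs_validation_cancer,validation,no,30
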