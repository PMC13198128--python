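task,cell,count
dppiv,train_pos,532
dppiv,train_neg,532
dppiv,test_pos,133
dppiv,test_neg,133
neuropeptide,train_pos,1940
neuropeptide,train_neg,1940
neuropeptide,test_pos,485
neuropeptide,test_neg,485
antiviral,train_pos,2321
antiviral,train_neg,2321
antiviral,test_pos,623
antiviral,test_neg,623
antioxidant,train_pos,582
antioxidant,train_neg,241
antioxidant,test_pos,28
antioxidant,test_neg,61
umami,train_pos,112
umami,train_neg,241
umami,test_pos,28
umami,test_neg,61
bbp,train_pos,100
bbp,train_neg,100
bbp,test_pos,19
bbp,test_neg,19
ttca,train_pos,470
ttca,train_neg,318
ttca,test_pos,122
ttca,test_neg,75
variant,train,100
variant,test,100
thermostability,train,936
thermostability,test,104
mic,train,3695
mic,test,924
acr,total,227
acr,pos,132
acr,neg,95
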