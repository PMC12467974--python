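class_name,split,count
Dyed Lifted Polyps,train,637
Dyed Lifted Polyps,validation,182
Dyed Lifted Polyps,test,93
Normal Z-line,train,582
Normal Z-line,validation,166
Normal Z-line,test,85
Dyed Resection Margins,train,366
Dyed Resection Margins,validation,104
Dyed Resection Margins,test,55
Normal Pylorus,train,569
Normal Pylorus,validation,162
Normal Pylorus,test,83
Normal Cecum,train,682
Normal Cecum,validation,195
Normal Cecum,test,99
Polyps,train,696
Polyps,validation,199
Polyps,test,100
Ulcerative Colitis,train,307
Ulcerative Colitis,validation,87
Ulcerative Colitis,test,45
Esophagitis,train,696
Esophagitis,validation,199
Esophagitis,test,101
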