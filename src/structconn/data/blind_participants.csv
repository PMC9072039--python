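subject_id,group,age,sex,blind_duration
EBA01,case,14,M,170
EBA02,case,16,M,194
EBA03,case,11,M,130
EBA04,case,14,F,166
EBA05,case,17,M,202
EBA06,case,15,M,180
EBA07,case,12,F,144
EBA08,case,16,F,192
EBA09,case,17,M,203
EBA10,case,17,F,205
EBA11,case,15,M,180
EBA12,case,18,M,213
EBA13,case,16,M,192
EBA14,case,17,M,204
EBA15,case,15,F,152
EBA16,case,17,F,196
EBA17,case,15,M,175
EBA18,case,15,M,179
EBA19,case,11,F,129
EBA20,case,13,M,159
EBA21,case,14,F,162
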