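source,role,shift,weekday,probability
bank,RN,early,mon,0.36
bank,RN,early,tue,0.36
bank,RN,early,wed,0.342
bank,RN,early,thu,0.342
bank,RN,early,fri,0.324
bank,RN,early,sat,0.288
bank,RN,early,sun,0.252
bank,RN,late,mon,0.315
bank,RN,late,tue,0.315
bank,RN,late,wed,0.299
bank,RN,late,thu,0.299
bank,RN,late,fri,0.284
bank,RN,late,sat,0.252
bank,RN,late,sun,0.22
bank,RN,night,mon,0.225
bank,RN,night,tue,0.225
bank,RN,night,wed,0.214
bank,RN,night,thu,0.214
bank,RN,night,fri,0.203
bank,RN,night,sat,0.18
bank,RN,night,sun,0.158
bank,NA,early,mon,0.4
bank,NA,early,tue,0.4
bank,NA,early,wed,0.38
bank,NA,early,thu,0.38
bank,NA,early,fri,0.36
bank,NA,early,sat,0.32
bank,NA,early,sun,0.28
bank,NA,late,mon,0.35
bank,NA,late,tue,0.35
bank,NA,late,wed,0.332
bank,NA,late,thu,0.332
bank,NA,late,fri,0.315
bank,NA,late,sat,0.28
bank,NA,late,sun,0.245
bank,NA,night,mon,0.25
bank,NA,night,tue,0.25
bank,NA,night,wed,0.237
bank,NA,night,thu,0.237
bank,NA,night,fri,0.225
bank,NA,night,sat,0.2
bank,NA,night,sun,0.175
agency,RN,early,mon,0.306
agency,RN,early,tue,0.306
agency,RN,early,wed,0.291
agency,RN,early,thu,0.291
agency,RN,early,fri,0.275
agency,RN,early,sat,0.245
agency,RN,early,sun,0.214
agency,RN,late,mon,0.268
agency,RN,late,tue,0.268
agency,RN,late,wed,0.254
agency,RN,late,thu,0.254
agency,RN,late,fri,0.241
agency,RN,late,sat,0.214
agency,RN,late,sun,0.187
agency,RN,night,mon,0.191
agency,RN,night,tue,0.191
agency,RN,night,wed,0.182
agency,RN,night,thu,0.182
agency,RN,night,fri,0.172
agency,RN,night,sat,0.153
agency,RN,night,sun,0.15
agency,NA,early,mon,0.34
agency,NA,early,tue,0.34
agency,NA,early,wed,0.323
agency,NA,early,thu,0.323
agency,NA,early,fri,0.306
agency,NA,early,sat,0.272
agency,NA,early,sun,0.238
agency,NA,late,mon,0.297
agency,NA,late,tue,0.297
agency,NA,late,wed,0.283
agency,NA,late,thu,0.283
agency,NA,late,fri,0.268
agency,NA,late,sat,0.238
agency,NA,late,sun,0.208
agency,NA,night,mon,0.212
agency,NA,night,tue,0.212
agency,NA,night,wed,0.202
agency,NA,night,thu,0.202
agency,NA,night,fri,0.191
agency,NA,night,sat,0.17
agency,NA,night,sun,0.15
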