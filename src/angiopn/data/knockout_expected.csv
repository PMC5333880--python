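unit,affected_percent
t12,85.42
m2,79.17
t18,66.67
m8,66.67
m11,66.67
m9,60.42
m7,60.42
m1,58.33
t30,58.33
t65,54.17
m5,45.83
t16,45.83
t71,45.83
t73,45.83
t69,33.33
m6,31.25
t51,29.17
m4,29.17
t27,29.17
t59,22.92
m3,16.67
t70,12.50
t64,4.17
t49,2.08
m10,2.08
t40,2.08
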