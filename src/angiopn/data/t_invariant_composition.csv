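invariant,mct_sets,single_transitions
x1,m10,
x2,m7,t49
x3,m9 m11,t40
x4,m6 m11,t59
x5,m3,t64 t65 t73
x6,m2 m8,t12 t18 t30 t51 t69 t73
x7,m3,t12 t16 t64 t65
x8,m2 m8,t12 t16 t18 t30 t51 t65 t69
x9,m3,t65 t70 t71 t73
x10,m2 m6,t12 t18 t51 t69 t71 t73
x11,m1 m2 m6 m7 m9 m11,t12 t27 t69 t71 t73
x12,m1 m2 m4 m6 m7 m8 m9 m11,t12 t69 t71 t73
x13,m2 m5 m6,t12 t18 t51 t71 t73
x14,m1 m2 m5 m6 m7 m9 m11,t12 t27 t71 t73
x15,m1 m2 m4 m5 m6 m7 m8 m9 m11,t12 t71 t73
x16,m1 m2 m7 m8 m9 m11,t12 t18 t27 t30 t69 t71 t73
x17,m1 m2 m4 m7 m8 m9 m11,t12 t18 t30 t69 t71 t73
x18,m1 m2 m5 m7 m8 m9 m11,t12 t18 t27 t30 t71 t73
x19,m1 m2 m4 m5 m7 m8 m9 m11,t12 t18 t30 t71 t73
x20,m3,t12 t16 t65 t70 t71
x21,m2 m6,t12 t16 t18 t51 t65 t69 t71
x22,m1 m2 m6 m7 m9 m11,t12 t16 t27 t65 t69 t71
x23,m1 m2 m4 m6 m7 m8 m9 m11,t12 t16 t65 t69 t71
x24,m2 m5 m6,t12 t16 t18 t51 t65 t71
x25,m1 m2 m5 m6 m7 m9 m11,t12 t16 t27 t65 t71
x26,m1 m2 m4 m5 m6 m7 m8 m9 m11,t12 t16 t65 t71
x27,m1 m2 m7 m8 m9 m11,t12 t16 t18 t27 t30 t65 t69 t71
x28,m1 m2 m4 m7 m8 m9 m11,t12 t16 t18 t30 t65 t69 t71
x29,m1 m2 m5 m7 m8 m9 m11,t12 t16 t18 t27 t30 t65 t71
x30,m1 m2 m4 m5 m7 m8 m9 m11,t12 t16 t18 t30 t65 t71
x31,m3 m8 m11,t18 t30 t59 t65 t70 t73
x32,m1 m2 m7 m8 m9 m11,t12 t18 t27 t30 t59 t69 t73
x33,m1 m2 m4 m7 m8 m9 m11,t12 t18 t30 t59 t69 t73
x34,m1 m2 m5 m7 m8 m9 m11,t12 t18 t27 t30 t59 t73
x35,m1 m2 m4 m5 m7 m8 m9 m11,t12 t18 t30 t59 t73
x36,m3 m8 m11,t12 t16 t18 t30 t59 t65 t70
x37,m1 m2 m7 m8 m9 m11,t12 t16 t18 t27 t30 t59 t65 t69
x38,m1 m2 m4 m7 m8 m9 m11,t12 t16 t18 t30 t59 t65 t69
x39,m1 m2 m5 m7 m8 m9 m11,t12 t16 t18 t27 t30 t59 t65
x40,m1 m2 m4 m5 m7 m8 m9 m11,t12 t16 t18 t30 t59 t65
x41,m2 m3 m5 m8,t12 t18 t30 t51 t65 t70 t73
x42,m2 m5 m6 m8,t12 t18 t30 t51 t73
x43,m1 m2 m5 m7 m8 m9 m11,t12 t18 t27 t30 t51 t73
x44,m1 m2 m4 m5 m7 m8 m9 m11,t12 t18 t30 t51 t73
x45,m2 m3 m5 m8,t12 t16 t18 t30 t51 t65 t70
x46,m2 m5 m6 m8,t12 t16 t18 t30 t51 t65
x47,m1 m2 m5 m7 m8 m9 m11,t12 t16 t18 t27 t30 t51 t65
x48,m1 m2 m4 m5 m7 m8 m9 m11,t12 t16 t18 t30 t51 t65
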