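set,transitions
m1,t19 t21 t22 t23 t24 t25 t28 t36 t37 t38 t41 t42 t43 t44 t45 t52 t53
m2,t0 t1 t2 t3 t4 t5 t7 t14 t20 t50 t68
m3,t8 t9 t10 t11 t17 t62 t63 t66 t67
m4,t6 t55 t56 t72
m5,t13 t15 t26
m6,t31 t33 t34
m7,t46 t47 t48
m8,t54 t57 t58
m9,t29 t39
m10,t32 t35
m11,t60 t61
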