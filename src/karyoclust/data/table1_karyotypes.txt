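MCF7	76 ~ 88 < 4n>,-X[11],-Xx2[8],-Xx3[4],der(X)t(X;15)(p11.2;q21)[16], der(X)t(X;15)(p11.2;q21)x2[3],der(X)dup(X)(q21qter)[5],-1[22]-1x2[2], der(1)t(1;21)t(9;21)[22],-2[13],-2x2[2],der(2)t(2;3)(q34;?)[19],-3[2], +3[17],del(3)(p14)[22],der(3)t(3;11)(p14;q13)[3],-4[12],-4x2[4], +5[2],-5[13],+6[9],+6x2[8],+6x3[4],add(6)(q27)[2],del(6)(q25)[4], del(6)(q25)x2[8], der(6)t(6;17;16)(q25;q21;?)[26], +7[26],der(7)t(1;7)(?;p15)[23],der(7)t(1;7)(?;p15)x2[2], del(7)(q11.2)[4],dup(7)(p13p15)[7],dup(7)(p13p15)x2[5],dup(7)(p13p15)x3[11],dup(7)(p14p15)[5],dup(7)(p14p15)x2[2],der(7)t(7;7)(p15;?)[19], der(7)t(7;7)(p15;?)[2],-8[8], -8x2[12],der(8)t(8;15)(p11;?)[26],+9[3] -9[7],-9x2[2],der(9)t(8;9)(q13;p22)[22],-10[6],-10x2[10],-10x3[3], der(10)t(7;10)(?;p14)[9],der(10)t(7;10)(?;p14)x2[12],-11[14], -11x2[12],del(11)(q23)[2],-12[15],-12x2[4],+12[2], del(12)(p11.2)(5),del(12)(q24)[11],der(12)t(8,12)(q11;p11)[15], -13[12],-13x2[10],-13x3[2],-14[3],+14[14],-15[12],-15x2[10], -15x3[3],-16[3],+16[16],der(16)t(8;16)(q?;q11.2)[8],der(16)t(8;16)(q?;q11.2) x2[17]der(16)t(16;19)(q21;?)[2],+17[11],+17x2[10],+17x3[5],der(17)t(8;17)t(1;8)[21],der(17)t(8;17)t(1;8)x2[5],der(17)t(17;19)(p11.1;p12)x2[17],-18[4], -18x2[14],-18x3[5],-18x4[3],-19[7],-19x2[15],-19x3[4], der(19)t(12;19)(q13;p13.3)[21],der(19)t(12;19)(q13;p13.3)x2[2],-20[2], -20x2[5],-20x3[11],-20x4[8],der(20)t(7;20)t(1;7)t(1;7)[21],+21[5],+21x2[2],-21[14],-21x2[2],+22[12],+22x2[3],-22[3],-22x2[2],add(22)(q13)[4][cp26]
T47D	57 ~ 66 < 3n>,X,-X[24],der(X)t(X;6)(q12;p11)[24],-1[19],-2[22], -3[5],del(3)(p11)[2],del(3)(p14)[2],del(3)(p21)[2],del(3)(q13)[6],del(3)(q22)[3], der(3)ins(3;5)(p14;q13q31)[2],der(3)del(3)(p13)del(3)(q13q25)ins(3;5)(q13;q13q31)[2], -4[19],-5[2],+5[3],-6[17],+7[3],del(7)(p21)[3],del(7)(p13p14)[5], del(7)(p13p14)x2[10],del(7)(p13p15)[8],der(7)t(7;15)(q21;q13)[3],dup(7)(p13p14)[2],+8[12],der(8;14)(q10;q10)x2[24],-9[11],-9x2[9],-10[11],-10x2[10],del(10)(p10)[3], der(10)t(3;10)(q?;q24)del(10)(p11.2)[14],der(10)t(3;10)(q?;q24)del(10)(p11.2)x2[10],+11[9],+11x2[7],+11x3[2],der(11)t(11;17)(q23;q?)t(9;17)(q?12;?)[2],-12[2],+12[6],+12x2[4], del(12)(p12)[6],del(12)(q24.1)[5],del(12)(q24.1)x2[3],der(12)del(12)(p12)del(12)(q24)[4], der(12)t(12;13)(p12;q22)[10],der(12)t(12;16)(p11.2;?)[11],-13[16],-13x2[4],+14[3],+14x2[13], +14x3[3],-15[6],-15x2[18],-16[2],der(16)t(1;16)(q12;q12)dup(1)(q21q43)[24], dic(9;17)t(9;17)(p12;p13)[13],dic(9;17)t(9;17)(p12;p13)x2[11],-18[17],-18x2[4],-19[18], +20[9],+20x2[3],der(20)t(10;20)(q21;q13.3)[15],der(20)t(10;20)(q21;q13.3)x2[9],der(20)del(20)(p11)t(10;20)(q21;q13.3)[10],+21[10],+21x2[6],-21[2], -22[14][cp24]
BT474	65 ~ 106 < 4n>,X,-X[9],-Xx2[5],-Xx3[4],der(X)t(X;17)(q13;q11q12)del(X)(p21) [9],der(X)t(X;18;X;12)[2],del(X)(q22)[14],-1[6],-1x2[2],+1[3],del(1)(p36.1)[6], -2[7],+2[7],der(2)t(1;2;7;20)(?;q31;?;?)[18],+3[12],-3[3],del(3)(p11.2)[7], del(3)(p14)[2],del(3)(q11.2)[6],del(3)(q11.2)x2[8],del(3)(q21)[4],del(3)(q13)[2], -4[8],-4x2[9],+4[2],-5[9],-5x2[9],+6[11],+6x3[3],-6[3], del(6)(q13)[3],del(6)(q21)[3],der(6)t(6;7)(q25;q31)[7],der(6)t(6;7)(q25;q31)x2[16],+7[4],+7x2[6],+7x3[9],+7x4[3],der(7)t(7;20)(p13;?)[5], der(7)t(1;7)(?;q11.2)[9], del(7)(q11.2)[7],del(7)(q11.2)x2[3],del(7)(q11.2)x3[3],der(7)t(7;14)(p13;p11.2)[4],-8[10], -9[7],-9x2[4],-9x3[2],der(9)t(3;9)(q33;?)[3],+10[6],-10[5], der(10)t(10;16;19)(q25;?;?)[11],i(10)(q10)[4],+11[9],+11x2[2],-11[3], der(11)t(8;11)(q21.1;p15)[2],der(11)t(8;17)(q21.1;q11q12)t(11;17)(p15;q11q12)[8],der(11)t(8;17)(q21.1;q11q12)t(11;17)(p15;q11q12)x2[12],der(11)t(8;17)(q21.1;q11q12)t(11;17)(p15;q11q12)x3[3],der(11)t(11;17)(q?14;?)t(8;17)(?;q?11.2)[13], der(11)t(11;17)(q?14;q?11.2)[9],+12[8], +12x2[5],del(12)(p11.1)[2],der(12)t(5;12)(q23;q23)[17],der(12)t(5;12)(q23;q23)x2[2],der(12)del(12)(p12)del(12)(q24)[3],-13[7],+13[6],+13x2[3],+13x4[2], der(13)t(13;17)(q10;q11q12)t(13;17)(q10;q11q12) [8],der(13)t(13;17)(q10;q11q12)t(13;17)(q10;q11q12)x2[12],+14[11], +14x2[3],+14x3[2],der(14)t(14;1;14)(q31;?;?)[6],der(14)t(14;1;14)(q31;?;?)x2[5], der(14)t(14;1;14)(q31;?;?)x3[9],der(14)t(14;1;14)(q31;?;?)x4[3], add(14)(p11.2)[2],der(14;14)(q10;q10)[3],der(14;14)(q10;q10)x2[16],-15[6],-15x2[9], -15x3[6],+16[7],+16x2[6],+16x3[3],-16[2],der(16)t(X;16)(q22;q24)[10], +17[16], der(17)t(6;17)(?;p13)t(15;17)(q11.2;q25)[22],-18[10],-18x2[4],-18x3[2],-19[6], -19x2[5],+19[5],-20[6],-20x2[6],+20[3],+20x3[2],der(20)t(19;20)(?;q10)[4], der(20)t(19;20)(?;q10)x2[5],+21[2],-21x2[11],-21x3[3],-22[2],-22x2[5],-22x3[2],-22x4[12], der(22)t(16;22)(q12;p11.2)[5][cp23]
SKBR3	76 ~ 83 < 4n>,XXX,-X[19],der(X)t(X;17)(q21;q?21)[15], der(X)t(X;8;17)(q13;q?21;?)[6],+1[8],+1x3[5],add(1)(p36.3)[4], del(1)(p13)[11],del(1)(p13)x2[6],del(1)(p34)[4],del(1)(p22)[9],del(1)(p36.1)[2], der(1)t(1;4)(q12;q12)[6],-2[6],-2x2[8],-2x3[3],der(2)t(2;6)(p13;?)[5],-3[10],-3x2[6],-4[8], -4x2[8],-4x3[3],der(4;14)t(4;14)(p11;p11.1)[3],-5[8], -5x2[8],-5x3[2],der(5)ins(5;15)(p13;q12q22)[6],-6[4],-6x2[12], -6x3[2],der(6)t(6;14;17)(q21;?;q11q12)del(6)(p23)[8],+7x2[8],+7x3[10], del(7)(q22)[12],del(7)(q32)[3],dup(7)(p14p15)[2],-8[6],+8[8], der(8)t(8;21)(?;?)t(8;21)(p23;?)t(8;21)(q24;?)[11],der(8)t(8;21)(?;?)t(8;21)(p23;?)t(8;21) (q24;?)x2[8],der(8)dup(8)(?)t(8;8)(?;p23)t(8;17)(q24;?)t(11;17)(?;?)[4], der(8;14)t(8;14)(p11.1;p11.1)[15],-9[9],-9x2[7],-10[4],-10x2[13],-10x3[2],+11[2],-11[7], add(11)(p15)[4],add(11)(q25)[2],-12[6],-12x2[5],+12[3],der(12)t(11;12)(p?;p12)[4], der(12)t(5;12)(q23;q23)[10],der(12)t(5;12)(q23;q23)x2[4],-13[6],-13x2[8], -13x3[3],der(13;13)(q11.2;q11.2)[16],-14[6],-14x2[4], der(14;14)(q11.2;q11.2)[18],-15[10],-15x2[7], dic(15;21)(p11.1;p11.1)[3], +16[4],-16[7],-17[3],+17[9],der(17;17)t(17;17)(q25;?)dup(17)(q22q25)t(17;20)(?;?)[5], der(17;17)t(17;17)(q25;?)dup(17)(q22q25)t(17;20)(?;?)x2[7], der(17;17)t(17;17)(q25;?)dup(17)(q22q25)t(17;20)(?;?)x3[7],del(17)(p11.2)[7], der(17)t(8;17)(q12;?)dup(17)(?)[19],der(17)t(8;17)(?;q25)dup(17) (q22q25)[5],der(17)t(8;17)(?;q25)dup(17)(q22q25)x2[2],der(17)t(8;13;14;17;21)(?;q?;q?;q11q12;?)[8],der(17)t(3;8;13;17;20)(?;?;q12;?p;?)[12],der(17)t(3;8;13;17;20)(?;?;q12;?p;?)x2[2],-18[3],-18x2[11],-18x3[5],der(18)t(18;22)(p11.2;?)[12],-19[4],-19x2[7],-20[8],-20x2[4], -20x3[7],-21[6],-21x2[3],-22[9],-22x2[4],+22[2],der(22)t(19,22)(q?;q13)[5][cp19]
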