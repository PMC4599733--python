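name,value,unit,temp_K,weight
a_b,33,d,271.5,1.0
a_j,165,d,271.5,1.0
L_b,0.04,cm,271.5,1.0
L_j,0.14,cm,271.5,1.0
L_p,2,cm,271.5,1.0
L_i,7,cm,271.5,1.0
L_i_f,6,cm,271.5,1.0
Wd_0,1.1,ug,271.5,1.0
W_p,2.95,g,271.5,1.0
W_i,100,g,271.5,1.0
W_i_f,50,g,271.5,1.0
GSI,0.10,-,271.5,1.0
PI,0.30,-,271.5,1.0
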