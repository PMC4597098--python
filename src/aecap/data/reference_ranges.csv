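lab_type,lln,uln,unit
K,3.5,5.1,mEq/L
NA,136,145,mmol/L
CA,8.4,10.2,mg/dL
MG,1.6,2.6,mg/dL
PO4,2.7,4.5,mg/dL
GLU,70,100,mg/dL
ALB,3.5,5.0,g/dL
TBIL,0.2,1.2,mg/dL
AST,10,40,U/L
ALT,7,56,U/L
ALP,44,147,U/L
GGT,9,48,U/L
CRE,0.6,1.2,mg/dL
AMY,28,100,U/L
LIP,13,60,U/L
WBC,4.0,11.0,10*9/L
HGB,12.0,16.0,g/dL
PLT,150,400,10*9/L
ANC,1.8,7.0,10*9/L
ALC,1.0,4.8,10*9/L
INR,0.8,1.2,ratio
APTT,25,35,s
FIB,200,400,mg/dL
UA,3.5,7.2,mg/dL
CHOL,120,200,mg/dL
TRIG,50,150,mg/dL
CPK,30,200,U/L
CD4,0.6,1.5,10*9/L
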