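lab_type,direction,ctcae_version,ae_term_id,meddra_code,unit,grade,lower_bound,upper_bound,context_dependent,clinical_only
K,low,4,hypokalemia,10021018,mEq/L,1,3.0,LLN,0,0
K,low,4,hypokalemia,10021018,mEq/L,3,2.5,3.0,0,0
K,low,4,hypokalemia,10021018,mEq/L,4,,2.5,0,0
K,low,4,hypokalemia,10021018,mEq/L,2,,,1,0
K,high,4,hyperkalemia,10020647,mEq/L,1,ULN,5.5,0,0
K,high,4,hyperkalemia,10020647,mEq/L,2,5.5,6.0,0,0
K,high,4,hyperkalemia,10020647,mEq/L,3,6.0,7.0,0,0
K,high,4,hyperkalemia,10020647,mEq/L,4,7.0,,0,0
NA,low,4,hyponatremia,10021038,mmol/L,1,130,LLN,0,0
NA,low,4,hyponatremia,10021038,mmol/L,3,120,130,0,0
NA,low,4,hyponatremia,10021038,mmol/L,4,,120,0,0
NA,high,4,hypernatremia,10020680,mmol/L,1,ULN,150,0,0
NA,high,4,hypernatremia,10020680,mmol/L,3,150,155,0,0
NA,high,4,hypernatremia,10020680,mmol/L,4,155,,0,0
NA,high,4,hypernatremia,10020680,mmol/L,2,,,1,0
CA,low,4,hypocalcemia,10020949,mg/dL,1,8.0,LLN,0,0
CA,low,4,hypocalcemia,10020949,mg/dL,2,7.0,8.0,0,0
CA,low,4,hypocalcemia,10020949,mg/dL,3,6.0,7.0,0,0
CA,low,4,hypocalcemia,10020949,mg/dL,4,,6.0,0,0
CA,high,4,hypercalcemia,10020587,mg/dL,1,ULN,11.5,0,0
CA,high,4,hypercalcemia,10020587,mg/dL,2,11.5,12.5,0,0
CA,high,4,hypercalcemia,10020587,mg/dL,3,12.5,13.5,0,0
CA,high,4,hypercalcemia,10020587,mg/dL,4,13.5,,0,0
MG,low,4,hypomagnesemia,10021028,mg/dL,1,1.2,LLN,0,0
MG,low,4,hypomagnesemia,10021028,mg/dL,2,0.9,1.2,0,0
MG,low,4,hypomagnesemia,10021028,mg/dL,3,0.7,0.9,0,0
MG,low,4,hypomagnesemia,10021028,mg/dL,4,,0.7,0,0
MG,high,4,hypermagnesemia,10020672,mg/dL,1,ULN,3.0,0,0
MG,high,4,hypermagnesemia,10020672,mg/dL,3,3.0,8.0,0,0
MG,high,4,hypermagnesemia,10020672,mg/dL,4,8.0,,0,0
PO4,low,4,hypophosphatemia,10021059,mg/dL,1,2.5,LLN,0,0
PO4,low,4,hypophosphatemia,10021059,mg/dL,2,2.0,2.5,0,0
PO4,low,4,hypophosphatemia,10021059,mg/dL,3,1.0,2.0,0,0
PO4,low,4,hypophosphatemia,10021059,mg/dL,4,,1.0,0,0
GLU,low,4,hypoglycemia,10020993,mg/dL,1,55,LLN,0,0
GLU,low,4,hypoglycemia,10020993,mg/dL,2,40,55,0,0
GLU,low,4,hypoglycemia,10020993,mg/dL,3,30,40,0,0
GLU,low,4,hypoglycemia,10020993,mg/dL,4,,30,0,0
GLU,high,4,hyperglycemia,10020635,mg/dL,1,ULN,160,0,0
GLU,high,4,hyperglycemia,10020635,mg/dL,2,160,250,0,0
GLU,high,4,hyperglycemia,10020635,mg/dL,3,250,500,0,0
GLU,high,4,hyperglycemia,10020635,mg/dL,4,500,,0,0
ALB,low,4,hypoalbuminemia,10020943,g/dL,1,3.0,LLN,0,0
ALB,low,4,hypoalbuminemia,10020943,g/dL,2,2.0,3.0,0,0
ALB,low,4,hypoalbuminemia,10020943,g/dL,3,,2.0,0,0
ALB,low,4,hypoalbuminemia,10020943,g/dL,4,,,1,0
TBIL,high,4,tbili_inc,10005364,mg/dL,1,ULN,1.8,0,0
TBIL,high,4,tbili_inc,10005364,mg/dL,2,1.8,3.6,0,0
TBIL,high,4,tbili_inc,10005364,mg/dL,3,3.6,12.0,0,0
TBIL,high,4,tbili_inc,10005364,mg/dL,4,12.0,,0,0
AST,high,4,ast_inc,10003481,U/L,1,ULN,120,0,0
AST,high,4,ast_inc,10003481,U/L,2,120,200,0,0
AST,high,4,ast_inc,10003481,U/L,3,200,800,0,0
AST,high,4,ast_inc,10003481,U/L,4,800,,0,0
ALT,high,4,alt_inc,10001551,U/L,1,ULN,168,0,0
ALT,high,4,alt_inc,10001551,U/L,2,168,280,0,0
ALT,high,4,alt_inc,10001551,U/L,3,280,1120,0,0
ALT,high,4,alt_inc,10001551,U/L,4,1120,,0,0
ALP,high,4,alp_inc,10001675,U/L,1,ULN,368,0,0
ALP,high,4,alp_inc,10001675,U/L,2,368,735,0,0
ALP,high,4,alp_inc,10001675,U/L,3,735,2940,0,0
ALP,high,4,alp_inc,10001675,U/L,4,2940,,0,0
GGT,high,4,ggt_inc,10017693,U/L,1,ULN,120,0,0
GGT,high,4,ggt_inc,10017693,U/L,2,120,240,0,0
GGT,high,4,ggt_inc,10017693,U/L,3,240,960,0,0
GGT,high,4,ggt_inc,10017693,U/L,4,960,,0,0
CRE,high,4,cre_inc,10011368,mg/dL,1,ULN,1.8,0,0
CRE,high,4,cre_inc,10011368,mg/dL,2,1.8,3.6,0,0
CRE,high,4,cre_inc,10011368,mg/dL,3,3.6,7.2,0,0
CRE,high,4,cre_inc,10011368,mg/dL,4,7.2,,0,0
AMY,high,4,amy_inc,10040375,U/L,1,ULN,150,0,0
AMY,high,4,amy_inc,10040375,U/L,2,150,200,0,0
AMY,high,4,amy_inc,10040375,U/L,3,200,500,0,0
AMY,high,4,amy_inc,10040375,U/L,4,500,,0,0
LIP,high,4,lip_inc,10024574,U/L,1,ULN,90,0,0
LIP,high,4,lip_inc,10024574,U/L,2,90,120,0,0
LIP,high,4,lip_inc,10024574,U/L,3,120,300,0,0
LIP,high,4,lip_inc,10024574,U/L,4,300,,0,0
WBC,low,4,wbc_dec,10049182,10*9/L,1,3.0,LLN,0,0
WBC,low,4,wbc_dec,10049182,10*9/L,2,2.0,3.0,0,0
WBC,low,4,wbc_dec,10049182,10*9/L,3,1.0,2.0,0,0
WBC,low,4,wbc_dec,10049182,10*9/L,4,,1.0,0,0
WBC,high,4,leukocytosis,10024378,10*9/L,3,100,,0,0
HGB,low,4,anemia,10002034,g/dL,1,10.0,LLN,0,0
HGB,low,4,anemia,10002034,g/dL,2,8.0,10.0,0,0
HGB,low,4,anemia,10002034,g/dL,3,,8.0,0,0
HGB,low,4,anemia,10002034,g/dL,4,,,1,0
PLT,low,4,plt_dec,10035528,10*9/L,1,75,LLN,0,0
PLT,low,4,plt_dec,10035528,10*9/L,2,50,75,0,0
PLT,low,4,plt_dec,10035528,10*9/L,3,25,50,0,0
PLT,low,4,plt_dec,10035528,10*9/L,4,,25,0,0
ANC,low,4,neut_dec,10029366,10*9/L,1,1.5,LLN,0,0
ANC,low,4,neut_dec,10029366,10*9/L,2,1.0,1.5,0,0
ANC,low,4,neut_dec,10029366,10*9/L,3,0.5,1.0,0,0
ANC,low,4,neut_dec,10029366,10*9/L,4,,0.5,0,0
ALC,low,4,lymph_dec,10025256,10*9/L,1,0.8,LLN,0,0
ALC,low,4,lymph_dec,10025256,10*9/L,2,0.5,0.8,0,0
ALC,low,4,lymph_dec,10025256,10*9/L,3,0.2,0.5,0,0
ALC,low,4,lymph_dec,10025256,10*9/L,4,,0.2,0,0
INR,high,4,inr_inc,10022402,ratio,1,ULN,1.5,0,0
INR,high,4,inr_inc,10022402,ratio,2,1.5,2.5,0,0
INR,high,4,inr_inc,10022402,ratio,3,2.5,,0,0
APTT,high,4,aptt_inc,10000636,s,1,ULN,52.5,0,0
APTT,high,4,aptt_inc,10000636,s,2,52.5,87.5,0,0
APTT,high,4,aptt_inc,10000636,s,3,87.5,,0,0
FIB,low,4,fibrinogen_dec,10016596,mg/dL,1,150,LLN,0,0
FIB,low,4,fibrinogen_dec,10016596,mg/dL,2,100,150,0,0
FIB,low,4,fibrinogen_dec,10016596,mg/dL,3,50,100,0,0
FIB,low,4,fibrinogen_dec,10016596,mg/dL,4,,50,0,0
UA,high,4,hyperuricemia,10020903,mg/dL,1,ULN,10.0,0,0
UA,high,4,hyperuricemia,10020903,mg/dL,3,10.0,,0,0
UA,high,4,hyperuricemia,10020903,mg/dL,4,,,1,0
CHOL,high,4,hypercholesterolemia,10020604,mg/dL,1,ULN,300,0,0
CHOL,high,4,hypercholesterolemia,10020604,mg/dL,2,300,400,0,0
CHOL,high,4,hypercholesterolemia,10020604,mg/dL,3,400,500,0,0
CHOL,high,4,hypercholesterolemia,10020604,mg/dL,4,500,,0,0
TRIG,high,4,hypertriglyceridemia,10020870,mg/dL,1,ULN,300,0,0
TRIG,high,4,hypertriglyceridemia,10020870,mg/dL,2,300,500,0,0
TRIG,high,4,hypertriglyceridemia,10020870,mg/dL,3,500,1000,0,0
TRIG,high,4,hypertriglyceridemia,10020870,mg/dL,4,1000,,0,0
CPK,high,4,cpk_inc,10011336,U/L,1,ULN,500,0,0
CPK,high,4,cpk_inc,10011336,U/L,2,500,1000,0,0
CPK,high,4,cpk_inc,10011336,U/L,3,1000,2000,0,0
CPK,high,4,cpk_inc,10011336,U/L,4,2000,,0,0
CD4,low,4,cd4_dec,10007800,10*9/L,1,0.5,LLN,0,0
CD4,low,4,cd4_dec,10007800,10*9/L,2,0.2,0.5,0,0
CD4,low,4,cd4_dec,10007800,10*9/L,3,0.05,0.2,0,0
CD4,low,4,cd4_dec,10007800,10*9/L,4,,0.05,0,0
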