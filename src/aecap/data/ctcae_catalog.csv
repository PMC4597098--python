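term_id,name,ctcae_version,system_organ_class,meddra_code,icd9_code,subheading,description
hypokalemia,Hypokalemia,4,Metabolism and nutrition disorders,10021018,276.8,electrolyte disorders,Serum potassium below the lower limit of normal
hyperkalemia,Hyperkalemia,4,Metabolism and nutrition disorders,10020647,276.7,electrolyte disorders,Serum potassium above the upper limit of normal
hyponatremia,Hyponatremia,4,Metabolism and nutrition disorders,10021038,276.1,electrolyte disorders,Serum sodium below the lower limit of normal
hypernatremia,Hypernatremia,4,Metabolism and nutrition disorders,10020680,276.0,electrolyte disorders,Serum sodium above the upper limit of normal
hypocalcemia,Hypocalcemia,4,Metabolism and nutrition disorders,10020949,275.41,electrolyte disorders,Serum calcium (corrected) below the lower limit of normal
hypercalcemia,Hypercalcemia,4,Metabolism and nutrition disorders,10020587,275.42,electrolyte disorders,Serum calcium (corrected) above the upper limit of normal
hypomagnesemia,Hypomagnesemia,4,Metabolism and nutrition disorders,10021028,275.2,electrolyte disorders,Serum magnesium below the lower limit of normal
hypermagnesemia,Hypermagnesemia,4,Metabolism and nutrition disorders,10020672,275.21,electrolyte disorders,Serum magnesium above the upper limit of normal
hypophosphatemia,Hypophosphatemia,4,Metabolism and nutrition disorders,10021059,275.3,electrolyte disorders,Serum phosphate below the lower limit of normal
hypoglycemia,Hypoglycemia,4,Metabolism and nutrition disorders,10020993,251.2,glucose disorders,Blood glucose below the lower limit of normal
hyperglycemia,Hyperglycemia,4,Metabolism and nutrition disorders,10020635,790.29,glucose disorders,Blood glucose above the upper limit of normal
hypoalbuminemia,Hypoalbuminemia,4,Metabolism and nutrition disorders,10020943,273.8,,Serum albumin below the lower limit of normal
hyperuricemia,Hyperuricemia,4,Metabolism and nutrition disorders,10020903,790.6,,Serum uric acid above the upper limit of normal
hypercholesterolemia,Hypercholesterolemia,4,Metabolism and nutrition disorders,10020604,272.0,lipid disorders,Serum cholesterol above the upper limit of normal
hypertriglyceridemia,Hypertriglyceridemia,4,Metabolism and nutrition disorders,10020870,272.1,lipid disorders,Serum triglycerides above the upper limit of normal
tbili_inc,Blood bilirubin increased,4,Investigations,10005364,,,Total bilirubin above the upper limit of normal
ast_inc,Aspartate aminotransferase increased,4,Investigations,10003481,,,AST above the upper limit of normal
alt_inc,Alanine aminotransferase increased,4,Investigations,10001551,,,ALT above the upper limit of normal
alp_inc,Alkaline phosphatase increased,4,Investigations,10001675,,,Alkaline phosphatase above the upper limit of normal
ggt_inc,GGT increased,4,Investigations,10017693,,,Gamma-glutamyltransferase above the upper limit of normal
cre_inc,Creatinine increased,4,Investigations,10011368,,,Serum creatinine above the upper limit of normal
amy_inc,Serum amylase increased,4,Investigations,10040375,,,Serum amylase above the upper limit of normal
lip_inc,Lipase increased,4,Investigations,10024574,,,Serum lipase above the upper limit of normal
wbc_dec,White blood cell decreased,4,Investigations,10049182,,,Total leukocyte count below the lower limit of normal
neut_dec,Neutrophil count decreased,4,Investigations,10029366,,,Absolute neutrophil count below the lower limit of normal
lymph_dec,Lymphocyte count decreased,4,Investigations,10025256,,,Absolute lymphocyte count below the lower limit of normal
plt_dec,Platelet count decreased,4,Investigations,10035528,,,Platelet count below the lower limit of normal
inr_inc,INR increased,4,Investigations,10022402,,,International normalized ratio above the upper limit of normal
aptt_inc,Activated partial thromboplastin time prolonged,4,Investigations,10000636,,,aPTT above the upper limit of normal
fibrinogen_dec,Fibrinogen decreased,4,Investigations,10016596,,,Plasma fibrinogen below the lower limit of normal
cpk_inc,CPK increased,4,Investigations,10011336,,,Creatine phosphokinase above the upper limit of normal
cd4_dec,CD4 lymphocytes decreased,4,Investigations,10007800,,,Absolute CD4+ lymphocyte count below the lower limit of normal
anemia,Anemia,4,Blood and lymphatic system disorders,10002034,285.9,,Hemoglobin below the lower limit of normal
leukocytosis,Leukocytosis,4,Blood and lymphatic system disorders,10024378,288.8,,Total leukocyte count above 100 x 10*9/L
afib,Atrial fibrillation,4,Cardiac disorders,10003658,427.31,arrhythmias,Irregularly irregular atrial rhythm
aflutter,Atrial flutter,4,Cardiac disorders,10003662,427.32,arrhythmias,Organized rapid atrial rhythm
svt,Supraventricular tachycardia,4,Cardiac disorders,10042604,427.0,arrhythmias,Rapid heart rhythm originating above the ventricles
sinus_brady,Sinus bradycardia,4,Cardiac disorders,10040741,427.81,arrhythmias,Sinus rhythm below 60 beats per minute
aortic_valve,Aortic valve disease,4,Cardiac disorders,10061583,424.1,valvular heart disease,Stenosis or insufficiency of the aortic valve
mitral_valve,Mitral valve disease,4,Cardiac disorders,10027727,424.0,valvular heart disease,Stenosis or insufficiency of the mitral valve
tricuspid_valve,Tricuspid valve disease,4,Cardiac disorders,10061389,424.2,valvular heart disease,Stenosis or insufficiency of the tricuspid valve
palpitations,Palpitations,4,Cardiac disorders,10033557,,,Subjective sensation of an irregular or forceful heartbeat
chest_pain_cardiac,Chest pain - cardiac,4,Cardiac disorders,10008481,,,Substernal discomfort of cardiac origin
nausea,Nausea,4,Gastrointestinal disorders,10028813,,,Queasy sensation and/or urge to vomit
vomiting,Vomiting,4,Gastrointestinal disorders,10047700,,,Reflexive ejection of stomach contents
diarrhea,Diarrhea,4,Gastrointestinal disorders,10012735,,,Increase in frequency and/or loose stools
nausea_v3,Nausea,3,Gastrointestinal disorders,10028813,,,Queasy sensation and/or urge to vomit
hypokalemia_v3,Hypokalemia,3,Metabolism and nutrition disorders,10021018,276.8,electrolyte disorders,Serum potassium below the lower limit of normal
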