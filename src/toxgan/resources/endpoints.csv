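code,name,category,units,wbc_component
ALP,alkaline phosphatase,clinical_chemistry,U/L,0
ALT,alanine aminotransferase,clinical_chemistry,U/L,0
AST,aspartate aminotransferase,clinical_chemistry,U/L,0
DBIL,direct bilirubin,clinical_chemistry,mg/dL,0
GTP,gamma-glutamyltranspeptidase,clinical_chemistry,U/L,0
LDH,lactate dehydrogenase,clinical_chemistry,U/L,0
TBIL,total bilirubin,clinical_chemistry,mg/dL,0
BUN,blood urea nitrogen,clinical_chemistry,mg/dL,0
Ca,calcium,clinical_chemistry,mg/dL,0
Cl,chlorine,clinical_chemistry,mEq/L,0
CRE,creatinine,clinical_chemistry,mg/dL,0
IP,inorganic phosphorus,clinical_chemistry,mg/dL,0
K,potassium,clinical_chemistry,mEq/L,0
Na,sodium,clinical_chemistry,mEq/L,0
A/G,albumin globulin ratio,clinical_chemistry,ratio,0
GLC,glucose,clinical_chemistry,mg/dL,0
PL,phospholipid,clinical_chemistry,mg/dL,0
RALB,albumin,clinical_chemistry,g/dL,0
TC,total cholesterol,clinical_chemistry,mg/dL,0
TG,triglyceride,clinical_chemistry,mg/dL,0
TP,total protein,clinical_chemistry,g/dL,0
APTT,activated partial thromboplastin time,hematology,s,0
Bas,basophil,hematology,%,1
Eos,eosinophil,hematology,%,1
Fbg,fibrinogen,hematology,mg/dL,0
Hb,hemoglobin,hematology,g/dL,0
Ht,hematocrit value,hematology,%,0
Lym,lymphocyte,hematology,%,1
MCH,mean corpuscular hemoglobin,hematology,pg,0
MCHC,mean corpuscular hemoglobin concentration,hematology,g/dL,0
MCV,mean corpuscular volume,hematology,fL,0
Mono,monocyte,hematology,%,1
Neu,neutrophil,hematology,%,1
Plat,platelet count,hematology,10^4/uL,0
PT,prothrombin time,hematology,s,0
RBC,red blood cell count,hematology,10^6/uL,0
Ret,reticulocyte,hematology,%,0
WBC,white blood cell count,hematology,10^2/uL,0
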