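# Default grouped-complaint phenotype map: phenotype -> keyword list.
# A complaint belongs to a phenotype when any keyword is a case-insensitive
# substring of its display string; the first-declared phenotype wins on
# overlapping hits.  Fifty cardiovascular-domain phenotypes are provided as
# a convention; replace with your own map for other domains.
heart failure: ["heart failure", "cardiac failure", "cardiac asthma"]
myocardial infarction: ["myocardial infarction", "post-myocardial"]
angina: ["angina"]
coronary artery disease: ["coronary arterioscl", "coronary heart", "myocardial ischemia"]
atrial fibrillation: ["atrial fibrillation", "atrial flutter"]
arrhythmia: ["arrhythmia", "premature ventricular", "premature cardiac", "parasystole"]
tachycardia: ["tachycardia"]
bradycardia: ["bradycardia"]
conduction disorder: ["conduction", "bundle-branch block", "atrioventricular block"]
cardiomyopathy: ["cardiomyopath"]
cardiomegaly: ["cardiomegaly", "cardiac dilatation"]
ventricular hypertrophy: ["ventricular hypertrophy", "concentric hypertrophy", "eccentric hypertrophy"]
valve disease: ["valve insufficiency", "valve stenosis", "valve disorder", "valve disease"]
aortic valve disease: ["aortic valve", "bicuspid aortic"]
mitral valve disease: ["mitral valve"]
endocarditis: ["endocarditis"]
myocarditis: ["myocarditis"]
pericarditis: ["pericarditis", "pericardial"]
congenital heart disease: ["congenital heart", "septal defect", "congenital abnormality"]
aneurysm: ["aneurysm", "dissection of aorta"]
hypertension: ["hypertens", "increase in blood pressure"]
hypotension: ["hypotens"]
atherosclerosis: ["atheroscler", "arterioscler", "plaque"]
carotid stenosis: ["carotid"]
stroke: ["stroke", "cerebrovascular accident"]
cerebrovascular disease: ["cerebral ischemia", "cerebral atheroscler", "encephalopath", "vertebrobasilar"]
thromboembolism: ["thromb", "embolism"]
peripheral vascular disease: ["peripheral vascular", "varicos"]
pulmonary hypertension: ["pulmonary hypertension", "pulmonary arterial hypertension"]
edema: ["edema", "swelling", "fluid overload", "effusion"]
dyspnea: ["dyspnea", "shortness of breath"]
syncope: ["syncope", "dizziness", "vertigo"]
chest pain: ["chest pain"]
palpitations: ["palpitation", "irregular heart beat"]
respiratory failure: ["respiratory insufficiency", "respiratory failure", "apnea"]
copd: ["chronic obstructive", "emphysema", "bronchitis"]
pneumonia: ["pneumonia", "lung consolidation"]
diabetes: ["diabet", "hyperglycemia", "glucose"]
obesity: ["obesity", "overweight"]
hyperlipidemia: ["lipid", "cholesterol", "dyslipidem"]
hyperuricemia: ["uricemia", "gout"]
chronic kidney disease: ["chronic kidney", "nephropathy", "nephroscler", "renal failure"]
kidney disease: ["kidney", "pyelonephritis", "microalbuminuria"]
anemia: ["anemia", "anaemia"]
thyroid disorder: ["thyroid", "goiter"]
liver disease: ["liver", "hepat", "cirrhosis"]
gastrointestinal disease: ["gastritis", "ulcer", "esophag", "hernia"]
decompensation: ["decompensat"]
cardiac arrest: ["cardiac arrest", "sudden cardiac death"]
pregnancy: ["pregnan", "childbirth", "obstetric"]
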