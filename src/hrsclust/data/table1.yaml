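# Per-cluster parameters for the hepatorenal-syndrome admission cohort
# (National Inpatient Sample 2003-2014, n = 5564), as printed in the source
# study's clinical-characteristics table. Binary rows give the count of
# admissions with the feature in each cluster; "*" marks cells suppressed
# under HCUP small-cell reporting rules (count below the reportable cutoff).
total_n: 5564
cluster_n:
  1: 1617
  2: 1577
  3: 642
  4: 1728

age:
  units: years
  mean: {1: 72.3, 2: 53.0, 3: 53.6, 4: 53.5}
  sd: {1: 8.4, 2: 8.3, 3: 10.2, 4: 9.5}

race:
  White: {1: 1320, 2: 1102, 3: 459, 4: 1340}
  Black: {1: 93, 2: 177, 3: 73, 4: 129}
  Hispanic: {1: 134, 2: 201, 3: 73, 4: 175}
  Other: {1: 70, 2: 97, 3: 37, 4: 84}

binary:
  Male sex: {1: 791, 2: 1050, 3: 402, 4: 1290}
  Weekend admission: {1: 361, 2: 287, 3: 131, 4: 330}
  Elective admission: {1: 157, 2: 182, 3: 0, 4: 179}
  Alcoholic cirrhosis: {1: 144, 2: 137, 3: 211, 4: 1589}
  Hepatitis B: {1: 29, 2: 77, 3: 21, 4: 22}
  Hepatitis C: {1: 104, 2: 709, 3: 137, 4: 258}
  NAFLD: {1: 756, 2: 240, 3: 59, 4: 12}
  Hepatocellular carcinoma: {1: 89, 2: 157, 3: 33, 4: 64}
  Acetaminophen overdose: {1: 12, 2: "*", 3: 181, 4: "*"}
  Acute liver failure: {1: 628, 2: 363, 3: 364, 4: 891}
  Smoking: {1: 52, 2: 100, 3: 18, 4: 276}
  Alcohol use: {1: 98, 2: 146, 3: 163, 4: 1389}
  Hypertension: {1: 780, 2: 414, 3: 117, 4: 427}
  Diabetes mellitus: {1: 632, 2: 315, 3: 42, 4: 195}
  Obesity: {1: 104, 2: 108, 3: 38, 4: 90}
  Hyperlipidemia: {1: 209, 2: 59, 3: 18, 4: 66}
  Chronic kidney disease: {1: 615, 2: 426, 3: 107, 4: 469}
  Congestive heart failure: {1: 426, 2: 109, 3: 63, 4: 81}
  Atrial fibrillation: {1: 261, 2: 35, 3: 32, 4: 72}
  Coronary artery disease: {1: 299, 2: 65, 3: 34, 4: 69}
  Anemia: {1: 487, 2: 573, 3: 169, 4: 669}
  Acute pancreatitis: {1: 49, 2: 65, 3: 59, 4: 119}
  GI bleeding: {1: 123, 2: 168, 3: 172, 4: 226}
  Cardiac arrest: {1: 46, 2: 36, 3: 67, 4: 38}
  Hypernatremia: {1: 44, 2: 47, 3: 38, 4: 42}
  Hyponatremia: {1: 342, 2: 607, 3: 241, 4: 802}
  Hyperkalemia: {1: 333, 2: 362, 3: 80, 4: 297}
  Hypokalemia: {1: 81, 2: 97, 3: 30, 4: 234}
  Acidosis: {1: 286, 2: 357, 3: 274, 4: 453}
  Alkalosis: {1: 19, 2: 32, 3: 14, 4: 24}
  Hypoglycemia: {1: 39, 2: 30, 3: 15, 4: 26}
  Sepsis: {1: 92, 2: 114, 3: 316, 4: 118}
  Circulatory failure: {1: 223, 2: 244, 3: 351, 4: 251}
  Respiratory failure: {1: 142, 2: 88, 3: 588, 4: 100}
  Neurological failure: {1: 123, 2: 115, 3: 88, 4: 121}
  Hematological failure: {1: 382, 2: 538, 3: 330, 4: 735}
  Renal replacement therapy: {1: 232, 2: 283, 3: 297, 4: 307}
  Non-invasive ventilation: {1: 24, 2: 22, 3: 32, 4: 16}
  Mechanical ventilation: {1: 35, 2: "*", 3: 504, 4: 26}
  Blood transfusion: {1: 319, 2: 525, 3: 372, 4: 545}
  Nutritional support: {1: 23, 2: 37, 3: 78, 4: 37}
  TIPS: {1: "*", 2: 19, 3: 15, 4: 12}
  DNR status: {1: 114, 2: 88, 3: 35, 4: 142}
  Palliative consult: {1: 244, 2: 173, 3: 76, 4: 255}

mortality:
  In-hospital mortality: {1: 545, 2: 392, 3: 449, 4: 470}
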