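descriptor	tree_numbers
Bacterial Infections	C01.252
Mycoses	C01.703
Virus Diseases	C02
HIV Infections	C02.782.815.616.400
Influenza, Human	C02.782.620.365
Parasitic Diseases	C03
Malaria	C03.752.530
Neoplasms	C04
Breast Neoplasms	C04.588.180
Lung Neoplasms	C04.588.894.797.520
Colorectal Neoplasms	C04.588.274.476.411
Musculoskeletal Diseases	C05
Osteoporosis	C05.116.198.579
Digestive System Diseases	C06
Liver Cirrhosis	C06.552.630
Respiratory Tract Diseases	C08
Asthma	C08.127.108
Pulmonary Disease, Chronic Obstructive	C08.381.495.389
Nervous System Diseases	C10
Stroke	C10.228.140.300.775
Alzheimer Disease	C10.228.140.380.100
Parkinson Disease	C10.228.140.079.862
Eye Diseases	C11
Cataract	C11.510.245
Cardiovascular Diseases	C14
Myocardial Infarction	C14.280.647.500
Hypertension	C14.907.489
Coronary Artery Disease	C14.280.647.250.260
Heart Failure	C14.280.434
Hemic and Lymphatic Diseases	C15
Anemia	C15.378.071
Congenital Abnormalities	C16.131
Skin Diseases	C17.800
Nutritional and Metabolic Diseases	C18
Obesity	C18.654.726.500
Diabetes Mellitus, Type 2	C18.452.394.750.149
Endocrine System Diseases	C19
Thyroid Diseases	C19.874
Immune System Diseases	C20
Autoimmune Diseases	C20.111
Wounds and Injuries	C26
Fractures, Bone	C26.404
Metabolism	G03
Lipid Metabolism	G03.493
Genetic Phenomena	G05
Polymorphism, Genetic	G05.365.590.762
Genetic Predisposition to Disease	G05.380
Gene Frequency	G05.365.590.175.380
Microbiological Phenomena	G06
Drug Resistance, Microbial	G06.099.375
Physiological Phenomena	G07
Aging	G07.345.124
Reproductive Physiological Phenomena	G08.686
Pregnancy	G08.686.785.760
Circulatory and Respiratory Physiological Phenomena	G09
Blood Pressure	G09.330.380.076
Immune System Phenomena	G12
Antibody Formation	G12.100
Mathematical Concepts	G17
Risk Factors	G17.680.750
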