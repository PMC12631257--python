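pt,soc
Abscess,Infections and infestations
Anal abscess,Infections and infestations
Abdominal abscess,Infections and infestations
Rectal abscess,Infections and infestations
Infected fistula,Infections and infestations
Lower respiratory tract infection,Infections and infestations
Upper respiratory tract infection,Infections and infestations
Nasopharyngitis,Infections and infestations
Pneumonia,Infections and infestations
Urinary tract infection,Infections and infestations
Kidney infection,Infections and infestations
Cellulitis,Infections and infestations
Gastrointestinal infection,Infections and infestations
Clostridium difficile infection,Infections and infestations
Postoperative wound infection,Infections and infestations
Abdominal pain,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Intestinal obstruction,Gastrointestinal disorders
Haematochezia,Gastrointestinal disorders
Fistula,Gastrointestinal disorders
Frequent bowel movements,Gastrointestinal disorders
Intestinal stenosis,Gastrointestinal disorders
Crohn's disease,Gastrointestinal disorders
Ulcerative colitis,Gastrointestinal disorders
Off label use,"Injury, poisoning and procedural complications"
Product dose omission issue,"Injury, poisoning and procedural complications"
Accidental exposure to product,"Injury, poisoning and procedural complications"
Infusion related reaction,"Injury, poisoning and procedural complications"
Fatigue,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Injection site pain,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Condition aggravated,General disorders and administration site conditions
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Migraine,Nervous system disorders
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Psoriasis,Skin and subcutaneous tissue disorders
Arthralgia,Musculoskeletal and connective tissue disorders
Back pain,Musculoskeletal and connective tissue disorders
Rheumatoid arthritis,Musculoskeletal and connective tissue disorders
Psoriatic arthropathy,Musculoskeletal and connective tissue disorders
Myocardial infarction,Cardiac disorders
Cardiac failure,Cardiac disorders
Palpitations,Cardiac disorders
Cholelithiasis,Hepatobiliary disorders
Cholangitis,Hepatobiliary disorders
Hepatic function abnormal,Hepatobiliary disorders
Skin cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Basal cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Transitional cell carcinoma recurrent,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Cough,"Respiratory, thoracic and mediastinal disorders"
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Drug level decreased,Investigations
Weight decreased,Investigations
Faecal calprotectin increased,Investigations
Anxiety,Psychiatric disorders
Depression,Psychiatric disorders
Hypertension,Vascular disorders
Vision blurred,Eye disorders
Anaemia,Blood and lymphatic system disorders
Nephrolithiasis,Renal and urinary disorders
Hypersensitivity,Immune system disorders
Decreased appetite,Metabolism and nutrition disorders
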