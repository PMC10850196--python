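disease,pt
Interstitial lung disease,Interstitial lung disease
Interstitial lung disease,Eosinophilic pneumonia
Interstitial lung disease,Lung disorder
Interstitial lung disease,Pneumonitis
Interstitial lung disease,Organizing pneumonia
Interstitial lung disease,Pulmonary fibrosis
Interstitial lung disease,Idiopathic pulmonary fibrosis
Hepatic function abnormal,Hepatic function abnormal
Hepatic function abnormal,Liver disorder
Hepatic function abnormal,Drug-induced liver injury
Anaphylactic reaction,Anaphylactic shock
Anaphylactic reaction,Anaphylactic reaction
Anaphylactic reaction,Shock
Anaphylactic reaction,Blood pressure decreased
Anaphylactic reaction,Urticaria
Platelet count decreased,Thrombocytopenia
Platelet count decreased,Platelet count decreased
Rhabdomyolysis,Rhabdomyolysis
Erythema multiforme,Erythema multiforme
Toxic epidermal necrolysis,Toxic skin eruption
Toxic epidermal necrolysis,Toxic epidermal necrolysis
Agranulocytosis,Agranulocytosis
Agranulocytosis,Granulocytopenia
Agranulocytosis,Granulocyte count decreased
Hepatitis fulminant,Hepatitis fulminant
Ileus,Ileus
Ileus,Intestinal obstruction
Ileus,Ileus paralytic
Ileus,Mechanical ileus
Stevens-Johnson syndrome,Stevens-Johnson syndrome
Stevens-Johnson syndrome,Oculomucocutaneous syndrome
Pancytopenia,Pancytopenia
Cardiac failure congestive,Cardiac failure congestive
Cardiac failure congestive,Cardiac failure
Acute generalized exanthematous pustulosis,Acute generalized exanthematous pustulosis
Acute kidney injury,Acute kidney injury
Pemphigoid,Pemphigoid
Hepatitis B reactivation,Hepatitis B
Hepatitis B reactivation,Hepatitis B DNA increased
Hepatitis B reactivation,Hepatitis B DNA assay positive
Hepatitis B reactivation,Hepatitis B virus test positive
Hepatitis B reactivation,Hepatitis B reactivation
Pancreatitis acute,Pancreatitis acute
Drug hypersensitivity,Drug reaction with eosinophilia and systemic symptoms
Drug hypersensitivity,Drug hypersensitivity
Nephrotic syndrome,Nephrotic syndrome
Hypoglycemia,Blood glucose decreased
Hypoglycemia,Hypoglycemia
Hypoglycemia,Hypoglycemic seizure
Neuroleptic malignant syndrome,Neuroleptic malignant syndrome
Deep vein thrombosis,Deep vein thrombosis
Deep vein thrombosis,Pulmonary embolism
Hemophagocytic lymphohistiocytosis,Hemophagocytic lymphohistiocytosis
Shock symptom,Anaphylactoid shock
Shock symptom,Shock symptom
Hyponatremia,Blood sodium decreased
Hyponatremia,Hyponatremia
Hypotension,Hypotension
Neutropenia,Neutrophil count decreased
Neutropenia,Neutropenia
Neutropenia,Autoimmune neutropenia
Neutropenia,Idiopathic neutropenia
Neutropenia,Febrile neutropenia
Tubulointerstitial nephritis,Tubulointerstitial nephritis
Ventricular tachycardia,Ventricular tachycardia
Ventricular tachycardia,Ventricular tachyarrhythmia
Depressed level of consciousness,Depressed level of consciousness
Depressed level of consciousness,Loss of consciousness
Depressed level of consciousness,Altered state of consciousness
Depressed level of consciousness,Hallucination
Depressed level of consciousness,"Hallucination, visual"
Cholangitis sclerosing,Cholangitis sclerosing
Tuberculosis,Tuberculosis
Intestinal perforation,Ileal perforation
Intestinal perforation,Large intestine perforation
Intestinal perforation,Intestinal perforation
Intestinal perforation,Rectal perforation
Colitis ischemic,Colitis ischemic
Guillain-Barre syndrome,Guillain-Barre syndrome
Ketoacidosis,Diabetic ketoacidosis
Ketoacidosis,Ketoacidosis
Metabolic acidosis,Metabolic acidosis
Hypomagnesemia,Hypomagnesemia
Ovarian hyperstimulation syndrome,Ovarian hyperstimulation syndrome
Stomatitis,Stomatitis
Laryngospasm,Laryngospasm
Enteritis,Enteritis
Acute respiratory distress syndrome,Acute respiratory distress syndrome
Acute disseminated encephalomyelitis,Acute disseminated encephalomyelitis
Cholecystitis acute,Cholecystitis acute
Inappropriate antidiuretic hormone secretion,Inappropriate antidiuretic hormone secretion
Disseminated intravascular coagulation,Disseminated intravascular coagulation
Sepsis,Bacterial sepsis
Sepsis,Sepsis
Sepsis,Septic shock
Neonatal cardiac failure,Cardiac failure high output
Neonatal cardiac failure,Neonatal cardiac failure
Pneumothorax,Pneumothorax
Gastrointestinal perforation,Gastrointestinal perforation
Gastrointestinal perforation,Upper gastrointestinal perforation
Gastrointestinal perforation,Lower gastrointestinal perforation
Hemolytic anemia,Autoimmune hemolytic anemia
Hemolytic anemia,Hemolytic anemia
Meningitis aseptic,Meningitis aseptic
Hyperthyroidism,Hyperthyroidism
Hypothyroidism,Thyroiditis
Hypothyroidism,Hypothyroidism
Leukoencephalopathy,Posterior reversible encephalopathy syndrome
Leukoencephalopathy,Progressive multifocal leukoencephalopathy
Leukoencephalopathy,Leukoencephalopathy
Hepatic failure,Hepatic failure
Gastric antral vascular ectasia,Gastric antral vascular ectasia
Gastric ulcer,Gastroduodenal ulcer
Gastric ulcer,Gastric ulcer
Gastric ulcer,Duodenal ulcer
Gastric ulcer,Gastric ulcer hemorrhage
Gastric ulcer,Duodenal ulcer hemorrhage
Cerebral infarction,Thrombotic cerebral infarction
Cerebral infarction,Cerebellar infarction
Cerebral infarction,Cerebral infarction
Cerebral infarction,Hemorrhagic cerebral infarction
Cerebral infarction,Embolic cerebral infarction
Cerebral infarction,Ischemic cerebral infarction
Nephrogenic diabetes insipidus,Nephrogenic diabetes insipidus
Renal impairment,Renal impairment
Pyelonephritis,Pyelonephritis acute
Pyelonephritis,Pyelonephritis
Tumor lysis syndrome,Tumor lysis syndrome
Tendon rupture,Tendon rupture
Thrombotic microangiopathy,Thrombotic microangiopathy
Optic neuritis,Optic neuritis
Myasthenia gravis,Myasthenia gravis
Myasthenia gravis,Myasthenia gravis crisis
Copper deficiency,Blood copper decreased
Copper deficiency,Copper deficiency
Deafness,Mixed deafness
Deafness,Deafness neurosensory
Deafness,Deafness
Osteomalacia,Osteomalacia
Hyperkaliemia,Blood potassium increased
Hyperkaliemia,Hyperkaliemia
Hyperglycemia,Hyperglycemia
Type 1 diabetes mellitus,Type 1 diabetes mellitus
Type 1 diabetes mellitus,Fulminant type 1 diabetes mellitus
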