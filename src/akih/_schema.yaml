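# Versioned column schema for the cohort interchange files.
# Types: id, date (YYYY-MM-DD), timestamp (YYYY-MM-DDTHH), float, int,
# bool ("true"/"false"), category (case-sensitive exact strings).
# The null marker is the empty field.
version: 1
patients:
  patient_id: id
  registration_date: date
  sex: category
  birth_date: date
  maintenance_dialysis: bool
  age_at_diagnosis: float
  height: float
  weight: float
  body_mass_index: float
  systolic_bp: float
  diastolic_bp: float
  hemoglobin: float
  albumin: float
  total_protein: float
  sodium: float
  potassium: float
  chloride: float
  glucose: float
  blood_urea_nitrogen: float
  cholesterol: float
  triglyceride: float
  uric_acid: float
  platelet: float
  white_blood_cell: float
  first_egfr: float
  follow_up_duration: float
  diabetes: bool
  hypertension: bool
  tuberculosis: bool
  chronic_liver_disease: bool
  smoking: bool
  surgery_yn: bool
  chemotherapy_yn: bool
  ct_scan_yn: bool
  dialysis_yn: bool
  hd_yn: bool
  pd_yn: bool
  crrt_yn: bool
  ktpl_yn: bool
  hd_date: date
  ktpl_date: date
  occupation: category
  income_level: category
  educational_status: category
  cancer_code: category
scr:
  patient_id: id
  time: timestamp
  value: float
  age_at_measurement: float
ct:
  patient_id: id
  date: date
iv_chemo:
  patient_id: id
  date: date
  nephrotoxicity: category
oral_chemo:
  patient_id: id
  date: date
  nephrotoxicity: category
nephrotoxic:
  patient_id: id
  date: date
  drug_group: category
  duration_days: int
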