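# Editable formulary: (diagnosis, age band) -> drug / dosage / frequency.
# The codomain is closed over the 10-drug, 14-dosage and 10-frequency
# vocabularies the recommender is trained on. `alternate` is the
# substitution used when the primary drug is blocked by a
# contraindication or a high-risk interaction with a background
# medication. `smoking_current` overrides apply to active smokers.
age_bands:
  child: [1, 11]
  adult: [12, 64]
  elderly: [65, 95]
rules:
  healthy:
    child:   {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
    adult:   {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
    elderly: {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
  asthma:
    child:
      drug: Budesonide
      dosage: 0.5 mg
      frequency: Twice daily
      alternate: {drug: Albuterol, dosage: 2 puffs, frequency: Every 4 to 6 h (PRN)}
    adult:
      drug: Fluticasone
      dosage: 88 mcg
      frequency: Twice daily
      alternate: {drug: Albuterol, dosage: 2 puffs, frequency: Every 4 to 6 h (PRN)}
    elderly:
      drug: Fluticasone
      dosage: 88 mcg
      frequency: Twice daily
      alternate: {drug: Albuterol, dosage: 2 puffs, frequency: Every 4 to 6 h (PRN)}
  COPD:
    child:
      drug: Albuterol
      dosage: 0.63-1.25 mg
      frequency: 3 to 4 times
    adult:
      drug: Tiotropium
      dosage: 1 puff (18 mcg)
      frequency: Once daily
      alternate: {drug: Albuterol, dosage: 2 puffs, frequency: Every 4 to 6 h (PRN)}
    elderly:
      drug: Tiotropium
      dosage: 1 puff (18 mcg)
      frequency: Once daily
      alternate: {drug: Albuterol, dosage: 2 puffs, frequency: Every 4 to 6 h (PRN)}
  pneumonia:
    child:
      drug: Amoxicillin
      dosage: 90 mg/kg/day
      frequency: Divided in 2 doses
    adult:
      drug: Amoxicillin
      dosage: 500 mg
      frequency: Every 8 h
    elderly:
      drug: Doxycycline
      dosage: 100 mg
      frequency: Twice daily for 7-14 days
      alternate: {drug: Amoxicillin, dosage: 250 mg, frequency: Every 8 h}
  URTI:
    child:   {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
    adult:
      drug: Ibuprofen
      dosage: 400 mg
      frequency: Every 6 to 8 h (PRN)
      smoking_current: {dosage: 400-600 mg}
      alternate: {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
    elderly:
      drug: Ibuprofen
      dosage: 400 mg
      frequency: Every 6 to 8 h (PRN)
      alternate: {drug: Supportive Care Only, dosage: N/A, frequency: N/A}
  LRTI:
    child:
      drug: Azithromycin
      dosage: 10 mg/kg
      frequency: Once daily for 3-5 days
      alternate: {drug: Amoxicillin, dosage: 90 mg/kg/day, frequency: Divided in 2 doses}
    adult:
      drug: Azithromycin
      dosage: 500 mg
      frequency: Once daily for 3-5 days
      alternate: {drug: Amoxicillin, dosage: 500 mg, frequency: Every 8 h}
    elderly:
      drug: Azithromycin
      dosage: 250 mg
      frequency: Once daily for 3-5 days
      alternate: {drug: Amoxicillin, dosage: 250 mg, frequency: Every 8 h}
  bronchiectasis:
    child:
      drug: Azithromycin
      dosage: 10 mg/kg
      frequency: Once daily for 3-5 days
      alternate: {drug: Amoxicillin, dosage: 90 mg/kg/day, frequency: Divided in 2 doses}
    adult:
      drug: Azithromycin
      dosage: 250 mg
      frequency: Once daily
      alternate: {drug: Amoxicillin, dosage: 500 mg, frequency: Every 8 h}
    elderly:
      drug: Azithromycin
      dosage: 250 mg
      frequency: Once daily
      alternate: {drug: Amoxicillin, dosage: 250 mg, frequency: Every 8 h}
  bronchiolitis:
    child:
      drug: Hypertonic Saline
      dosage: 4 mL of 7% saline
      frequency: 3 to 4 times
    adult:
      drug: Albuterol
      dosage: 2 puffs
      frequency: Every 4 to 6 h (PRN)
    elderly:
      drug: Albuterol
      dosage: 2 puffs
      frequency: Every 4 to 6 h (PRN)
contraindications:
  # drug classes never dispensed for a diagnosis (beta-blockers in asthma);
  # none of these appear in the rules above, the filter enforces it anyway.
  asthma: [Propranolol, Metoprolol, Atenolol, Carvedilol, Bisoprolol]
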