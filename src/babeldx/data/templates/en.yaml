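language: en
header_text: |
  I am running an experiment on a clinical case description to see how your
  diagnoses compare with those of human specialists. The case below is that of
  a patient with a genetic disease. Based on the phenotypic findings, return
  the differential diagnosis as an ordered list of candidate diagnoses, with
  the most likely diagnosis first.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: ""
sex_age_frames:
  FEMALE:
    aged: "The patient was a {age} female."
    unaged: "The patient was a female."
  MALE:
    aged: "The patient was a {age} male."
    unaged: "The patient was a male."
  UNKNOWN:
    aged: "The patient was a {age} individual."
    unaged: "The patient was an individual of unspecified age."
observed_frame: "The patient presented with {features}."
excluded_frame: "The following findings were excluded: {features}."
onset_frame: "As a {onset}, the patient presented with {features}."
list_separator: ", "
final_conjunction: " and "
age_phrase_rules:
  year: "{n}-year-old"
  month: "{n}-month-old"
  day: "{n}-day-old"
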