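language: nl
header_text: |
  Ik voer een experiment uit met een klinische casusbeschrijving om te zien
  hoe uw diagnoses zich verhouden tot die van menselijke specialisten. De
  onderstaande casus betreft een patiënt met een genetische ziekte. Geef op
  basis van de fenotypische bevindingen de differentiaaldiagnose terug als een
  geordende lijst van kandidaatdiagnoses, de meest waarschijnlijke eerst.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Geef de differentiaaldiagnose in het Engels."
sex_age_frames:
  FEMALE:
    aged: "De patiënt was een vrouw van {age}."
    unaged: "De patiënt was een vrouw."
  MALE:
    aged: "De patiënt was een man van {age}."
    unaged: "De patiënt was een man."
  UNKNOWN:
    aged: "De patiënt was een persoon van {age}."
    unaged: "De patiënt was een persoon van niet-gespecificeerde leeftijd."
observed_frame: "De patiënt presenteerde zich met {features}."
excluded_frame: "De volgende bevindingen werden uitgesloten: {features}."
onset_frame: "Op de leeftijd van {onset} presenteerde de patiënt zich met {features}."
list_separator: ", "
final_conjunction: " en "
age_phrase_rules:
  year: "{n} jaar"
  month: "{n} maanden"
  day: "{n} dagen"
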