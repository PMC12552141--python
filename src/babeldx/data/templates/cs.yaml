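language: cs
header_text: |
  Provádím experiment s popisem klinického případu, abych porovnal vaše
  diagnózy s diagnózami lidských specialistů. Níže uvedený případ se týká
  pacienta s genetickým onemocněním. Na základě fenotypových nálezů vraťte
  diferenciální diagnózu jako uspořádaný seznam kandidátních diagnóz,
  nejpravděpodobnější jako první.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Vraťte prosím diferenciální diagnózu v angličtině."
sex_age_frames:
  FEMALE:
    aged: "Pacientkou byla žena ve věku {age}."
    unaged: "Pacientkou byla žena."
  MALE:
    aged: "Pacientem byl muž ve věku {age}."
    unaged: "Pacientem byl muž."
  UNKNOWN:
    aged: "Pacientem byla osoba ve věku {age}."
    unaged: "Pacientem byla osoba neuvedeného věku."
observed_frame: "Pacient se prezentoval těmito nálezy: {features}."
excluded_frame: "Následující nálezy byly vyloučeny: {features}."
onset_frame: "Ve věku {onset} se u pacienta objevily tyto nálezy: {features}."
list_separator: ", "
final_conjunction: " a "
age_phrase_rules:
  year: "{n} let"
  month: "{n} měsíců"
  day: "{n} dnů"
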