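language: it
header_text: |
  Sto conducendo un esperimento sulla descrizione di un caso clinico per
  confrontare le sue diagnosi con quelle di specialisti umani. Il caso
  seguente riguarda un paziente con una malattia genetica. Sulla base dei
  reperti fenotipici, restituisca la diagnosi differenziale come elenco
  ordinato di diagnosi candidate, la più probabile per prima.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Restituisca la diagnosi differenziale in inglese."
sex_age_frames:
  FEMALE:
    aged: "La paziente era una donna di {age}."
    unaged: "La paziente era una donna."
  MALE:
    aged: "Il paziente era un uomo di {age}."
    unaged: "Il paziente era un uomo."
  UNKNOWN:
    aged: "Il paziente era una persona di {age}."
    unaged: "Il paziente era una persona di età non specificata."
observed_frame: "Il paziente presentava {features}."
excluded_frame: "I seguenti reperti sono stati esclusi: {features}."
onset_frame: "All'età di {onset}, il paziente ha presentato {features}."
list_separator: ", "
final_conjunction: " e "
age_phrase_rules:
  year: "{n} anni"
  month: "{n} mesi"
  day: "{n} giorni"
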