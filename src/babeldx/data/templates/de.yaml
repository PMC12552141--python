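language: de
header_text: |
  Ich führe ein Experiment mit einer klinischen Fallbeschreibung durch, um zu
  sehen, wie Ihre Diagnosen mit denen menschlicher Fachärzte übereinstimmen.
  Der folgende Fall betrifft einen Patienten mit einer genetischen Erkrankung.
  Geben Sie auf Grundlage der phänotypischen Befunde die Differentialdiagnose
  als geordnete Liste von Kandidatendiagnosen zurück, die wahrscheinlichste
  zuerst.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Bitte geben Sie die Differentialdiagnose auf Englisch zurück."
sex_age_frames:
  FEMALE:
    aged: "Die Patientin war eine Frau im Alter von {age}."
    unaged: "Die Patientin war eine Frau."
  MALE:
    aged: "Der Patient war ein Mann im Alter von {age}."
    unaged: "Der Patient war ein Mann."
  UNKNOWN:
    aged: "Der Fall betrifft eine Person im Alter von {age}."
    unaged: "Der Fall betrifft eine Person, deren Alter nicht angegeben war."
observed_frame: "Der Patient zeigte {features}."
excluded_frame: "Die folgenden Befunde wurden ausgeschlossen: {features}."
onset_frame: "Im Alter von {onset} zeigte der Patient {features}."
list_separator: ", "
final_conjunction: " und "
age_phrase_rules:
  year: "{n} Jahren"
  month: "{n} Monaten"
  day: "{n} Tagen"
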