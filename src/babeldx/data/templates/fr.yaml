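language: fr
header_text: |
  Je mène une expérience sur la description d'un cas clinique afin de comparer
  vos diagnostics à ceux de spécialistes humains. Le cas ci-dessous est celui
  d'un patient atteint d'une maladie génétique. Sur la base des signes
  phénotypiques, renvoyez le diagnostic différentiel sous forme de liste
  ordonnée de diagnostics candidats, le plus probable en premier.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Veuillez renvoyer le diagnostic différentiel en anglais."
sex_age_frames:
  FEMALE:
    aged: "La patiente était une femme de {age}."
    unaged: "La patiente était une femme."
  MALE:
    aged: "Le patient était un homme de {age}."
    unaged: "Le patient était un homme."
  UNKNOWN:
    aged: "Le patient était une personne de {age}."
    unaged: "Le patient était une personne d'âge non précisé."
observed_frame: "Le patient présentait {features}."
excluded_frame: "Les signes suivants ont été exclus : {features}."
onset_frame: "À l'âge de {onset}, le patient a présenté {features}."
list_separator: ", "
final_conjunction: " et "
age_phrase_rules:
  year: "{n} ans"
  month: "{n} mois"
  day: "{n} jours"
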