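language: es
header_text: |
  Estoy realizando un experimento con la descripción de un caso clínico para
  comparar sus diagnósticos con los de especialistas humanos. El caso
  siguiente corresponde a un paciente con una enfermedad genética. Con base en
  los hallazgos fenotípicos, devuelva el diagnóstico diferencial como una
  lista ordenada de diagnósticos candidatos, el más probable primero.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Devuelva el diagnóstico diferencial en inglés."
sex_age_frames:
  FEMALE:
    aged: "La paciente era una mujer de {age}."
    unaged: "La paciente era una mujer."
  MALE:
    aged: "El paciente era un hombre de {age}."
    unaged: "El paciente era un hombre."
  UNKNOWN:
    aged: "El paciente era una persona de {age}."
    unaged: "El paciente era una persona de edad no especificada."
observed_frame: "El paciente presentaba {features}."
excluded_frame: "Se excluyeron los siguientes hallazgos: {features}."
onset_frame: "A la edad de {onset}, el paciente presentó {features}."
list_separator: ", "
final_conjunction: " y "
age_phrase_rules:
  year: "{n} años"
  month: "{n} meses"
  day: "{n} días"
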