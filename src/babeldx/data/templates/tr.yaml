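language: tr
header_text: |
  Tanılarınızı insan uzmanların tanılarıyla karşılaştırmak için bir klinik
  vaka tanımı üzerinde deney yürütüyorum. Aşağıdaki vaka genetik bir hastalığı
  olan bir hastaya aittir. Fenotipik bulgulara dayanarak, ayırıcı tanıyı en
  olasıdan başlayarak sıralı bir aday tanı listesi olarak döndürün.
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "Lütfen ayırıcı tanıyı İngilizce olarak döndürün."
sex_age_frames:
  FEMALE:
    aged: "Hasta {age} bir kadındı."
    unaged: "Hasta bir kadındı."
  MALE:
    aged: "Hasta {age} bir erkekti."
    unaged: "Hasta bir erkekti."
  UNKNOWN:
    aged: "Hasta {age} bir bireydi."
    unaged: "Hastanın yaşı belirtilmemişti."
observed_frame: "Hastada {features} görüldü."
excluded_frame: "Şu bulgular dışlandı: {features}."
onset_frame: "{onset} iken hastada {features} görüldü."
list_separator: ", "
final_conjunction: " ve "
age_phrase_rules:
  year: "{n} yaşında"
  month: "{n} aylık"
  day: "{n} günlük"
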