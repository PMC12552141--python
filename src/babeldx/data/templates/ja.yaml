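language: ja
header_text: |
  臨床症例記述に関する実験を行っており、あなたの診断を専門医の診断と
  比較します。以下の症例は遺伝性疾患の患者です。表現型所見に基づき、
  候補診断を可能性の高い順に並べた順序付きリストとして鑑別診断を
  返してください。
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "鑑別診断は英語で返してください。"
sex_age_frames:
  FEMALE:
    aged: "患者は{age}の女性であった。"
    unaged: "患者は女性であった。"
  MALE:
    aged: "患者は{age}の男性であった。"
    unaged: "患者は男性であった。"
  UNKNOWN:
    aged: "患者は{age}の個人であった。"
    unaged: "患者の年齢は記載されていなかった。"
observed_frame: "患者には{features}がみられた。"
excluded_frame: "以下の所見は除外された:{features}。"
onset_frame: "{onset}の時点で、患者には{features}がみられた。"
list_separator: "、"
final_conjunction: "および"
age_phrase_rules:
  year: "{n}歳"
  month: "生後{n}か月"
  day: "生後{n}日"
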