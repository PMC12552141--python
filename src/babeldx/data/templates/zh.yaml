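language: zh
header_text: |
  我正在进行一项临床病例描述实验,以比较您的诊断与人类专科医生的诊断。
  以下病例是一名遗传病患者。请根据表型发现,以有序列表形式返回鉴别诊断的
  候选诊断,最可能的诊断排在首位。
example_output_block: |
  The example output format is:
  1. Marfan syndrome
  2. Ehlers-Danlos syndrome
  3. Loeys-Dietz syndrome
english_reply_instruction: "请用英语返回鉴别诊断。"
sex_age_frames:
  FEMALE:
    aged: "患者为{age}女性。"
    unaged: "患者为女性。"
  MALE:
    aged: "患者为{age}男性。"
    unaged: "患者为男性。"
  UNKNOWN:
    aged: "患者为{age}个体。"
    unaged: "患者为一名个体,年龄未说明。"
observed_frame: "患者表现出{features}。"
excluded_frame: "排除了以下表现:{features}。"
onset_frame: "患者在{onset}时出现{features}。"
list_separator: "、"
final_conjunction: "和"
age_phrase_rules:
  year: "{n}岁"
  month: "{n}个月大"
  day: "{n}天大"
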