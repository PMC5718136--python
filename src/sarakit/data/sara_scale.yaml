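# Canonical SARA scale definition: 8 items, three clinical dimensions,
# total score 0-40 (bilateral items contribute the mean of both sides).
items:
  - item_id: gait
    min_score: 0
    max_score: 8
    bilateral: false
    binding: gait_ataxia
    cluster: gait_and_balance
  - item_id: stance
    min_score: 0
    max_score: 6
    bilateral: false
    binding: standing_instability
    cluster: gait_and_balance
  - item_id: sitting
    min_score: 0
    max_score: 4
    bilateral: false
    binding: sitting_instability
    cluster: gait_and_balance
  - item_id: speech
    min_score: 0
    max_score: 6
    bilateral: false
    binding: dysarthria
    cluster: speech_disturbance
  - item_id: finger_chase
    min_score: 0
    max_score: 4
    bilateral: true
    binding: limb_dysmetria
    cluster: limb_coordination
  - item_id: nose_finger
    min_score: 0
    max_score: 4
    bilateral: true
    binding: intention_tremor
    cluster: limb_coordination
  - item_id: alternating_hand
    min_score: 0
    max_score: 4
    bilateral: true
    binding: dysdiadochokinesis
    cluster: limb_coordination
  - item_id: heel_shin
    min_score: 0
    max_score: 4
    bilateral: true
    binding: lower_limb_dysmetria
    cluster: limb_coordination
cluster_bindings:
  gait_and_balance: truncal_ataxia
  speech_disturbance: dysarthria
  limb_coordination: appendicular_ataxia
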