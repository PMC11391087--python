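# Default adult neuropsychological battery: 7 cognitive domains x 3 outcome
# measures.  direction says which tail is impaired; generator_family is the
# marginal used by the synthetic-cohort sampler.
domains:
  - name: verbal_reasoning
    measures: [similarities, vocabulary, information]
  - name: perceptual_skills
    measures: [block_design, matrix_reasoning, rocf_copy]
  - name: memory
    measures: [logical_memory, word_list, rocf_recall]
  - name: working_memory
    measures: [digit_span_forward, digit_span_backward, digit_span_sequencing]
  - name: attention
    measures: [cpt_omissions, cpt_rt_variability, flanker_cost]
  - name: executive_function
    measures: [cpt_commissions, stroop_interference, word_fluency]
  - name: speed
    measures: [cpt_rt, coding, pegboard_time]

measures:
  - {name: similarities, domain: verbal_reasoning, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Similarities total score"}
  - {name: vocabulary, domain: verbal_reasoning, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Vocabulary total score"}
  - {name: information, domain: verbal_reasoning, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Information"}
  - {name: block_design, domain: perceptual_skills, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Block Design"}
  - {name: matrix_reasoning, domain: perceptual_skills, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Matrix Reasoning"}
  - {name: rocf_copy, domain: perceptual_skills, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "ROCF copy score"}
  - {name: logical_memory, domain: memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WMS-III Logical Memory I+II summed"}
  - {name: word_list, domain: memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WMS-III Word List total + delayed summed"}
  - {name: rocf_recall, domain: memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "ROCF immediate + delayed accuracy summed"}
  - {name: digit_span_forward, domain: working_memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Digit Span Forward"}
  - {name: digit_span_backward, domain: working_memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Digit Span Backward"}
  - {name: digit_span_sequencing, domain: working_memory, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Digit Span Sequencing"}
  - {name: cpt_omissions, domain: attention, direction: higher_worse,
     transform: none, generator_family: count,
     display_label: "CPT omission errors"}
  - {name: cpt_rt_variability, domain: attention, direction: higher_worse,
     transform: none, generator_family: lognormal,
     display_label: "CPT reaction time variability"}
  - {name: flanker_cost, domain: attention, direction: higher_worse,
     transform: none, generator_family: lognormal,
     display_label: "Flanker conflict cost (ms)"}
  - {name: cpt_commissions, domain: executive_function, direction: higher_worse,
     transform: none, generator_family: count,
     display_label: "CPT commission errors"}
  - {name: stroop_interference, domain: executive_function, direction: higher_worse,
     transform: none, generator_family: lognormal,
     display_label: "Stroop interference time (s)"}
  - {name: word_fluency, domain: executive_function, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "Word fluency (animals + letter K)"}
  - {name: cpt_rt, domain: speed, direction: higher_worse,
     transform: none, generator_family: normal,
     display_label: "CPT mean reaction time (ms)"}
  - {name: coding, domain: speed, direction: higher_better,
     transform: none, generator_family: normal,
     display_label: "WAIS-IV Coding total score"}
  - {name: pegboard_time, domain: speed, direction: higher_worse,
     transform: none, generator_family: normal,
     display_label: "Nine-Hole Peg Test best time (s)"}
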