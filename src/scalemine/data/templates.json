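{
  "mention": [
    "Mental health status was assessed using the {scale}.",
    "Participants completed the {scale} at baseline.",
    "Symptoms were measured with the {scale} in an online survey.",
    "We used the {scale} to examine psychological distress.",
    "Scores on the {scale} indicated an elevated symptom burden."
  ],
  "title": [
    "Psychological distress among {population} during the COVID-19 pandemic",
    "Mental health and wellbeing of {population} under lockdown restrictions",
    "Anxiety and depressive symptoms in {population}: an observational report",
    "Sleep quality and stress in {population} during the COVID-19 outbreak"
  ],
  "title_mention": [
    "Validation of the {scale} in {population} during the COVID-19 pandemic",
    "Screening {population} with the {scale}: a COVID-19 report",
    "Psychometric properties of the {scale} among {population}"
  ],
  "populations": [
    "nurses", "students", "pregnant women", "older adults",
    "frontline workers", "the general population", "adolescents",
    "hospital staff", "caregivers", "university students"
  ],
  "filler": [
    "Anxiety and depressive symptoms were widespread during lockdown.",
    "Respondents were recruited through an online platform.",
    "Elevated stress was associated with reduced sleep quality.",
    "Psychological support services were offered to all participants.",
    "Symptom severity declined over the follow-up period."
  ],
  "distractor": [
    "The World Health Organization declared a public health emergency.",
    "a sliding scale of doses was applied in the intervention arm",
    "Data were analyzed with the Statistical Package for the Social Sciences (SPSS).",
    "The National Wellness Monitoring Survey framework guided sampling.",
    "Ethics approval was granted by the University Institutional Review Board."
  ]
}
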