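# Default entity lexicon for English ICH emergency-record narratives.
#
# Each entry maps surface patterns (applied to preprocessed, lowercased text)
# to one CaseFacts field.  Numeric entries name a `value` capture group (and
# optionally a `unit` group); enumerated entries attach a fixed `value` per
# pattern.  `negatable` entries flip to `negated_value` when a negation cue
# ("no", "not", "without", "denies", "denied", "absent") occurs in the same
# clause; symptom mentions in a negated clause are simply excluded from the
# symptom set.

abbreviations:
  pt: patient
  c/o: complains of
  hr: heart rate
  bp: blood pressure
  spo2: oxygen saturation
  o2sat: oxygen saturation
  b/l: bilateral
  hx: history
  y/o: year old

misspellings:
  headach: headache
  headake: headache
  nausia: nausea
  vomitting: vomiting
  anisocoira: anisocoria
  anisocora: anisocoria
  ganglai: ganglia
  ganlia: ganglia
  thalamas: thalamus
  cerebelum: cerebellum
  midlin: midline
  ventricals: ventricles
  ventriculer: ventricular
  stabel: stable
  deterioating: deteriorating
  detereorating: deteriorating
  drowsey: drowsy
  commatose: comatose
  stuporus: stuporous
  alret: alert
  puplis: pupils
  rective: reactive
  babinsky: babinski
  heamatoma: hematoma
  hematomma: hematoma
  shiftd: shifted
  presure: pressure
  saturaton: saturation
  hemorrage: hemorrhage
  hemorhage: hemorrhage
  unconsious: unconscious

entries:
  - label: gcs_total
    target: gcs_total
    normalizer: int
    patterns:
      - re: 'gcs\s(?:score\s)?(?:of\s|was\s|is\s)?(?P<value>\d{1,2})\b'

  - label: gcs_eye
    target: gcs_eye
    normalizer: int
    patterns:
      - re: '\be(?P<value>[1-4])(?=v[1-5]m[1-6]\b)'

  - label: gcs_verbal
    target: gcs_verbal
    normalizer: int
    patterns:
      - re: '(?<=e[1-4])v(?P<value>[1-5])(?=m[1-6]\b)'

  - label: gcs_motor
    target: gcs_motor
    normalizer: int
    patterns:
      - re: '(?<=v[1-5])m(?P<value>[1-6])\b'

  - label: heart_rate
    target: heart_rate
    normalizer: int
    patterns:
      - re: 'heart rate\s(?:of\s|was\s|is\s)?(?P<value>\d{2,3})\b'
      - re: 'pulse\s(?:of\s|was\s|is\s)?(?P<value>\d{2,3})\b'

  - label: systolic_bp
    target: systolic_bp
    normalizer: int
    patterns:
      - re: 'blood pressure\s(?:of\s|was\s|is\s)?(?P<value>\d{2,3})(?=\s?/)'

  - label: diastolic_bp
    target: diastolic_bp
    normalizer: int
    patterns:
      - re: '(?<=/)\s?(?P<value>\d{2,3})\s?mmhg'

  - label: spo2
    target: spo2
    normalizer: int
    patterns:
      - re: 'oxygen saturation\s(?:of\s|was\s|is\s)?(?P<value>\d{2,3})\s?%?'

  - label: consciousness
    target: consciousness_grade
    patterns:
      - re: '\balert\b'
        value: alert
      - re: '\bdrowsy\b|\blethargic\b'
        value: drowsy
      - re: '\bstupor(?:ous)?\b'
        value: stupor
      - re: '\bcomatose\b|\bcoma\b(?!\sscale)|\bunconscious\b'
        value: coma

  - label: pathological_reflex
    target: pathological_reflex
    negatable: true
    negated_value: absent
    patterns:
      - re: 'babinski(?:\ssign)?(?:\spresent|\spositive)?'
        value: present
      - re: 'pathological\sreflex(?:es)?(?:\spresent|\selicited)?'
        value: present

  - label: pupil_state
    target: pupil_state
    patterns:
      - re: 'pupils?\s(?:are\s)?equal(?:\sand\s(?:briskly\s)?reactive(?:\sto\slight)?)?'
        value: equal_reactive
      - re: 'anisocoria|pupils?\s(?:are\s)?unequal|unequal\spupils?'
        value: anisocoria
      - re: 'pupils?\s(?:are\s)?fixed\sand\sdilated|fixed\sdilated\spupils?'
        value: bilateral_fixed_dilated

  - label: symptom
    target: symptoms
    negatable: true
    patterns:
      - re: '\bheadache\b'
        value: headache
      - re: '\bnausea\b'
        value: nausea
      - re: '\bvomit(?:ing|ed|s)?\b'
        value: vomiting

  - label: bleed_location
    target: bleed_location
    patterns:
      - re: 'basal\sganglia'
        value: basal_ganglia
      - re: 'thalam(?:us|ic)'
        value: thalamus
      - re: '(?:frontal|temporal|parietal|occipital)\slobe|\blobar\b'
        value: lobar
      - re: 'cerebell(?:um|ar)'
        value: cerebellum
      - re: '\bbrainstem\b|\bpontine\b|\bpons\b'
        value: brainstem
      - re: 'intraventricular\shemorrhage'
        value: intraventricular_primary

  - label: laterality
    target: laterality
    patterns:
      - re: '\bleft\b'
        value: left
      - re: '\bright\b'
        value: right
      - re: '\bbilateral\b'
        value: bilateral

  - label: hematoma_volume
    target: hematoma_volume_ml
    normalizer: volume_ml
    patterns:
      - re: '\b(?P<value>\d+(?:\.\d+)?)\s?(?P<unit>ml|cc)\b'

  - label: ventricle_cast
    target: ventricle_cast
    negatable: true
    negated_value: absent
    patterns:
      - re: 'ventricular\ssystem\sis\scast|ventricles?\s(?:are\s)?(?:cast|filled)\swith\sblood|casting\sof\sthe\sventricles'
        value: present

  - label: ventricle_shape
    target: ventricle_shape_abnormal
    negatable: true
    negated_value: absent
    patterns:
      - re: 'ventricles?\s(?:are\s)?(?:compressed|deformed|effaced)(?:\sand\s(?:compressed|deformed|effaced))?'
        value: present
      - re: 'ventricles?\s(?:are\s)?normal\sin\ssize\sand\sshape'
        value: absent

  - label: midline_shift
    target: midline_shift_mm
    normalizer: length_mm
    patterns:
      - re: 'midline(?:\sstructures?)?\s(?:is\s|are\s)?shift(?:ed|ing)?\s(?:of\s|by\s)?(?:approximately\s|about\s)?(?P<value>\d+(?:\.\d+)?)\s?(?P<unit>mm|cm)'
      - re: 'midline\sshift\sof\s(?:approximately\s|about\s)?(?P<value>\d+(?:\.\d+)?)\s?(?P<unit>mm|cm)'
      - re: 'no\s(?:evidence\sof\s)?midline\sshift'
        value: 0.0

  - label: condition_trend
    target: condition_trend
    patterns:
      - re: 'deteriorat\w+|worsen\w+|progressive(?:ly)?\sdecline?\w*'
        value: deteriorating
      - re: '\bstable\b|stabilized'
        value: stable
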