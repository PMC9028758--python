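# Sentence templates for rendering CaseFacts into English eEMR narratives.
# One sentence per fact group; with all noise rates at zero the rendering is
# canonical and fully invertible by the default lexicon.

chief_complaint:
  opener: "a {age} year old {sex} patient presents to the emergency department."
  symptoms: "the patient complains of {symptoms}."

history:
  filler: "history of hypertension."
  trend:
    deteriorating: "the condition has been deteriorating since onset."
    stable: "the condition has remained stable since onset."

physical_exam:
  gcs_full: "gcs {total} (e{e}v{v}m{m})."
  gcs_total_only: "gcs {total}."
  consciousness:
    alert: "the patient is alert."
    drowsy: "the patient is drowsy."
    stupor: "the patient is stuporous."
    coma: "the patient is comatose."
  pupils:
    equal_reactive: "pupils are equal and reactive to light."
    anisocoria: "anisocoria is noted."
    bilateral_fixed_dilated: "pupils are fixed and dilated."
  reflex:
    present: "babinski sign present."
    absent: "no pathological reflex elicited."
  heart_rate: "heart rate {hr} per minute."
  blood_pressure: "blood pressure {sbp}/{dbp} mmhg."
  spo2: "oxygen saturation {spo2}%."
  filler: "general examination performed."

ct_report:
  bleeding: "ct shows hematoma of approximately {vol} {vol_unit} in the {site}."
  location_surface:
    basal_ganglia: "basal ganglia"
    thalamus: "thalamus"
    lobar: "frontal lobe"
    cerebellum: "cerebellum"
    brainstem: "brainstem"
    intraventricular_primary: "ventricular system (primary intraventricular hemorrhage)"
  cast:
    present: "the ventricular system is cast with blood."
    absent: "no casting of the ventricles."
  shape:
    present: "the ventricles are compressed and deformed."
    absent: "the ventricles are normal in size and shape."
  shift: "midline structures shifted by {mm} {unit}."
  no_shift: "no midline shift."
  filler: "imaging reviewed."
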