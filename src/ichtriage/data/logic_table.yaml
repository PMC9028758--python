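# Default logic table: guideline-derived ICH surgical-indication rules.
#
# Mandate rules force Plan I (emergency surgery) outright; weighted rules sum
# into a score normalised by the table's total weight and thresholded at
# cut_high (>= -> Plan I) and cut_low (>= -> Plan IIA, else Plan IIB).  Ties
# at a cut-point resolve toward the more aggressive plan.  Unknown fields
# never satisfy a comparator, so missing data cannot mandate surgery.
#
# Both volume-weighted rules are restricted to supratentorial locations so
# the score is monotone in hematoma volume at every location (cerebellar
# volume is handled by its own mandate; brainstem surgical indication is
# controversial and deliberately not a mandate here).

cut_high: 0.5
cut_low: 0.15

rules:
  - rule_id: cerebellar_volume
    mandate: true
    weight: 0
    when:
      - {field: bleed_location, op: eq, value: cerebellum}
      - {field: hematoma_volume_ml, op: ge, value: 10}

  - rule_id: cerebellar_ventricular_cast
    mandate: true
    weight: 0
    when:
      - {field: bleed_location, op: eq, value: cerebellum}
      - {field: ventricle_cast, op: eq, value: present}

  - rule_id: cerebellar_brainstem_compression
    mandate: true
    weight: 0
    when:
      - {field: bleed_location, op: eq, value: cerebellum}
      - {field: consciousness_grade, op: in, value: [stupor, coma]}

  - rule_id: supratentorial_mass_low_gcs
    mandate: true
    weight: 0
    when:
      - {field: bleed_location, op: in, value: [basal_ganglia, thalamus, lobar]}
      - {field: hematoma_volume_ml, op: ge, value: 30}
      - {field: gcs_total, op: le, value: 8}

  - rule_id: bilateral_fixed_pupils
    mandate: true
    weight: 0
    when:
      - {field: pupil_state, op: eq, value: bilateral_fixed_dilated}

  - rule_id: herniation_anisocoria_coma
    mandate: true
    weight: 0
    when:
      - {field: pupil_state, op: eq, value: anisocoria}
      - {field: consciousness_grade, op: eq, value: coma}

  - rule_id: supratentorial_large_volume
    weight: 3
    when:
      - {field: bleed_location, op: in, value: [basal_ganglia, thalamus, lobar]}
      - {field: hematoma_volume_ml, op: ge, value: 30}

  - rule_id: low_gcs
    weight: 3
    when:
      - {field: gcs_total, op: le, value: 8}

  - rule_id: midline_shift
    weight: 2
    when:
      - {field: midline_shift_mm, op: ge, value: 5}

  - rule_id: ventricular_cast
    weight: 2
    when:
      - {field: ventricle_cast, op: eq, value: present}

  - rule_id: deteriorating_course
    weight: 2
    when:
      - {field: condition_trend, op: eq, value: deteriorating}

  - rule_id: anisocoria
    weight: 2
    when:
      - {field: pupil_state, op: eq, value: anisocoria}

  - rule_id: supratentorial_moderate_volume
    weight: 1
    when:
      - {field: bleed_location, op: in, value: [basal_ganglia, thalamus, lobar]}
      - {field: hematoma_volume_ml, op: ge, value: 10}
      - {field: hematoma_volume_ml, op: lt, value: 30}

  - rule_id: moderate_gcs
    weight: 1
    when:
      - {field: gcs_total, op: ge, value: 9}
      - {field: gcs_total, op: le, value: 12}

  - rule_id: pathological_reflex
    weight: 1
    when:
      - {field: pathological_reflex, op: eq, value: present}
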