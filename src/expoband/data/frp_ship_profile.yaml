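# Worked-example situation profile: FRP lamination (UPR spraying/coating)
# for ship manufacturing, styrene, company A.  Selections use the
# abbreviated labels an assessor would enter; aliases in the factor table
# resolve them to the canonical classifications.
situation_id: FRP-A
task_label: FRP lamination for ship manufacturing
phase: liquid
selections:
  position_factor: General worker (manufacturing, assembly, etc.)
  potential_emission: >-
    Large amount of chemicals (in tons) is used with high pressure and speed
    resulting in generation of mist or spray/haze on large surfaces and
    workplaces
  historical_exposure: Samples were 10-50% of exposure limits
  process_type: Manual handling with low-level cleaning
  ventilation_containment: Fully ventilated with high-level containment
  localized_control: LEV is used, but some contaminants are not removed and remain
  ppe: 50% protection using PPE-1 and PPE-2
  health_hazard: Hazard category 2 (e.g., H305, H315, H319, etc.)
  task_duration: 1-4 h
  task_frequency: 4-5 days a week
  distance: "<=1 m"
  room_volume: ">1000 m3"
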