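# Effect-size term lexicon and trap-phrase list.
#
# `terms` maps each canonical effect-size type (OR, RR, HR) to the surface
# forms that report it: a case-sensitive acronym, adjusted-acronym variants
# (aOR, adj OR ...), and case-insensitive full wordings.  Wordings tolerate
# plural, hyphen or extra spaces ("hazard-ratio", "hazard ratios") and an
# optional "adjusted" prefix marking the adjusted flag.
#
# `traps` maps each acronym to full wordings that reuse it for a quantity
# that is NOT an effect size (e.g. "heart rate" for HR).  The presence of
# any trap wording in a text switches detection of that acronym to a
# restrictive procedure; bare-acronym mentions are then suppressed.
terms:
  OR:
    acronym: OR
    adjusted_acronyms: [aOR, adjOR]
    wordings:
      - odds ratio
  RR:
    acronym: RR
    adjusted_acronyms: [aRR, adjRR]
    wordings:
      - relative risk
      - risk ratio
      - rate ratio
      - relative rate
  HR:
    acronym: HR
    adjusted_acronyms: [aHR, adjHR]
    wordings:
      - hazard ratio
      - hazards ratio
traps:
  HR:
    - heart rate
    - heart rates
  RR:
    - respiratory rate
    - response rate
    - recovery rate
  OR:
    - ovulation rate
    - operating room
    - operative risk
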