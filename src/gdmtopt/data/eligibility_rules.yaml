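# Eligibility gating for GDMT scoring. Thresholds are evaluated strictly
# (potassium_gt: 5.0 fires when K+ > 5.0). A contraindication rule blocks the
# class entirely (removed from the score denominator); an escalation rule only
# blocks up-titration of a class already prescribed below target.
contraindication:
  MRA:
    potassium_gt: 5.0
    egfr_lt: 30
  SGLT2I:
    egfr_lt: 20
  RASI:
    potassium_gt: 5.5
    sbp_lt: 90
  BETA_BLOCKER:
    pulse_lt: 55
escalation_block:
  RASI:
    sbp_lt: 95
  BETA_BLOCKER:
    sbp_lt: 95
    pulse_lt: 60
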