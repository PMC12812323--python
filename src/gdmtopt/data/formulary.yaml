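# Default HFrEF GDMT formulary: guideline target total daily doses (mg/day) and
# usual titration ladders. Editable; drug names are matched case-insensitively.
# component_ratio applies only to fixed-ratio combination products (ARNI).
drugs:
  - name: lisinopril
    gdmt_class: RASI
    subtype: ACEI
    target_daily_dose: 40
    titration_steps: [5, 10, 20, 40]
  - name: enalapril
    gdmt_class: RASI
    subtype: ACEI
    target_daily_dose: 40
    titration_steps: [5, 10, 20, 40]
  - name: losartan
    gdmt_class: RASI
    subtype: ARB
    target_daily_dose: 150
    titration_steps: [25, 50, 100, 150]
  - name: valsartan
    gdmt_class: RASI
    subtype: ARB
    target_daily_dose: 320
    titration_steps: [80, 160, 320]
  - name: sacubitril/valsartan
    gdmt_class: RASI
    subtype: ARNI
    target_daily_dose: 400        # 97/103 mg twice daily = 194 mg sacubitril + 206 mg valsartan
    titration_steps: [100, 200, 400]
    component_ratio: {sacubitril: 0.485, valsartan: 0.515}
  - name: carvedilol
    gdmt_class: BETA_BLOCKER
    subtype: none
    target_daily_dose: 50
    titration_steps: [6.25, 12.5, 25, 50]
  - name: metoprolol succinate
    gdmt_class: BETA_BLOCKER
    subtype: none
    target_daily_dose: 200
    titration_steps: [25, 50, 100, 200]
  - name: bisoprolol
    gdmt_class: BETA_BLOCKER
    subtype: none
    target_daily_dose: 10
    titration_steps: [1.25, 2.5, 5, 10]
  - name: spironolactone
    gdmt_class: MRA
    subtype: none
    target_daily_dose: 25
    titration_steps: [12.5, 25]
  - name: eplerenone
    gdmt_class: MRA
    subtype: none
    target_daily_dose: 50
    titration_steps: [25, 50]
  - name: dapagliflozin
    gdmt_class: SGLT2I
    subtype: none
    target_daily_dose: 10
    titration_steps: [10]
  - name: empagliflozin
    gdmt_class: SGLT2I
    subtype: none
    target_daily_dose: 10
    titration_steps: [10]
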