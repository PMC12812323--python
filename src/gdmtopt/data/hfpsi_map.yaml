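# Default integer point map for the Heart Failure Patient Severity Index.
# One point per threshold exceeded on BUN/BNP, one point each for NYHA >= 3,
# diabetes, AF/flutter history and hospitalization within the prior 6 months;
# the point total is mapped onto the ordinal 1-4 severity class by `cuts`
# (class = 1 + number of cuts at or below the total). This map is a
# configurable stand-in: the published index's exact integer weights are not
# reproduced here and users with access to them should supply their own map.
bun_thresholds_mg_dl: [20, 30, 40]
bnp_thresholds_pg_ml: [300, 900, 1800]
nyha_point_at: 3
point_for_diabetes: 1
point_for_af_flutter: 1
point_for_recent_hospitalization: 1
cuts: [2, 4, 6]
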