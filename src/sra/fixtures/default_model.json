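{
 "kind": "linear_svm",
 "classes": [
  "AF",
  "NO_RISK",
  "PAF_RISK"
 ],
 "feature_names": [
  "sd1_ms",
  "sd2_ms",
  "sd_ratio",
  "dnorm_sd",
  "dnorm_p95",
  "extreme_window_ratio",
  "apen",
  "pac_countable_per_hour"
 ],
 "scale_mean": [
  61.59098586242194,
  84.93231972386121,
  0.6136580974578465,
  0.06649039340429078,
  0.12913418067829927,
  0.8213897648244798,
  1.598856674028022,
  175.3158752855311
 ],
 "scale_sd": [
  54.24918194363589,
  39.89841100674438,
  0.28615277040443243,
  0.06518024243526427,
  0.1270901722895869,
  0.17023123530230921,
  0.07316607464914945,
  230.63452584659652
 ],
 "coef": [
  [
   0.2356869721804413,
   0.15992911262821152,
   0.2264937205930554,
   0.2838017957274745,
   0.28325126653354193,
   -0.21910667401614806,
   -0.022377950197657013,
   0.34800446331227575
  ],
  [
   0.5089781650161778,
   -0.6774024447432067,
   -1.9080267684821701,
   -0.15160718922091185,
   -0.6849428043396958,
   0.629062530412043,
   -0.5985013910488607,
   -1.8006492340264755
  ],
  [
   -1.9143908554435838,
   1.6727274429828187,
   1.572412737847143,
   -1.4847816717225393,
   -0.6465690314060177,
   -0.048441279545876535,
   1.0529470316386649,
   -0.804659097200469
  ]
 ],
 "intercept": [
  -0.2529865292987107,
  -3.852543316742419,
  -0.8430033335626573
 ],
 "seed": 42,
 "version": "1"
}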