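{
 "cohort": {
  "seed": 20240408,
  "n_participants": 8,
  "tests_per_participant": 8,
  "n_traces": 64
 },
 "features": {
  "crows_median": {
   "mean": 1.6912301202205882,
   "sd": 0.12849109399855652
  },
  "curve_iqr": {
   "mean": 63.39384068980351,
   "sd": 8.002579578510522
  },
  "curve_mean": {
   "mean": 59.03563669857121,
   "sd": 6.14199236829625
  },
  "curve_sampen": {
   "mean": 1.914453061951265,
   "sd": 0.12972040245784572
  },
  "deltaheading_iqr": {
   "mean": 15.798749355626217,
   "sd": 1.2845702550441422
  },
  "deltaheading_mean": {
   "mean": -4.133386003338316,
   "sd": 7.647252583743103
  },
  "fs_iqr": {
   "mean": 0.0,
   "sd": 0.0
  },
  "fs_sampen": {
   "mean": 0.02153195960048227,
   "sd": 0.0285712435263328
  },
  "heading_sampen": {
   "mean": 0.4926287975701535,
   "sd": 0.21458720427742595
  },
  "heading_std": {
   "mean": 141.46750114529632,
   "sd": 32.75392580923192
  },
  "quality_sampen": {
   "mean": 1.9448625506950703,
   "sd": 0.21816493213101737
  },
  "speed_iqr": {
   "mean": 0.2409135275863069,
   "sd": 0.01739978221529684
  }
 }
}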