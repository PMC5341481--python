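{
 "window_length": 147,
 "K": [
  8.439292,
  10.368796,
  31.357069,
  23.726008,
  12.304942,
  10.759298,
  19.827993,
  7.686067,
  23.535642,
  43.729335,
  8.855554,
  44.447891,
  23.238466,
  6.235452,
  13.829602,
  38.499042
 ],
 "theta0": [
  0.118472,
  -0.104116,
  0.140357,
  -0.167919,
  -0.251043,
  -0.204063,
  -0.09594,
  -0.020884,
  -0.140147,
  0.189466,
  -0.184023,
  -0.222319,
  -0.245001,
  0.059141,
  0.212845,
  0.060973
 ],
 "kappa": 20.0,
 "amplitude": 0.2,
 "period": 10.0,
 "phase": 0.0,
 "lam": 0.0,
 "beta": 6.0
}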