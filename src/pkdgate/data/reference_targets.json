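{
  "t1": {"expected": 132.1, "tol": 0.5, "units": "mV",
         "what": "half-activation voltage recovered from noiseless whole-cell activation-curve points"},
  "t2": {"expected": 47.2, "tol": 0.5, "units": "mV",
         "what": "slope factor k recovered in the same activation-curve round trip"},
  "t5": {"expected": 11.64, "tol": 0.01, "units": "mV",
         "what": "zero crossing of the simulated steady-state WT current"},
  "t6": {"expected": 0.02, "tol": 0.0001, "units": "open fraction",
         "what": "WT steady-state activation at strongly hyperpolarised potential"},
  "t7": {"expected": 138.3, "tol": 1.0, "units": "mV",
         "what": "WT half-activation voltage recovered by the simulate-extract-fit pipeline"},
  "t8": {"expected": 182.7, "tol": 1.0, "units": "mV",
         "what": "K461Q half-activation voltage recovered by the same pipeline"},
  "t9": {"expected": 42.2, "tol": 0.5, "units": "mV",
         "what": "half-inactivation voltage recovered from noiseless availability points"}
}
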