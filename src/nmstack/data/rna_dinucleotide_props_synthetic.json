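{
 "version": 1,
 "note": "SYNTHETIC standardized placeholder values (mean 0, sd 1 over the 16 dinucleotides); not measured helical parameters. Supply a measured table via PseKncSpec(props=...) for physically meaningful correlation terms.",
 "properties": {
  "rise": {
   "AA": 0.358826,
   "AC": 1.027791,
   "AG": -0.997074,
   "AU": -0.694648,
   "CA": 1.004529,
   "CC": 1.721532,
   "CG": -1.94947,
   "CU": 0.266401,
   "GA": 0.534364,
   "GC": 0.380729,
   "GG": -0.363553,
   "GU": -1.735328,
   "UA": -0.653847,
   "UC": 1.214227,
   "UG": 0.018916,
   "UU": -0.133395
  },
  "roll": {
   "AA": 0.420712,
   "AC": -0.443087,
   "AG": 0.403847,
   "AU": -0.806591,
   "CA": -1.008662,
   "CC": -1.57534,
   "CG": 0.543468,
   "CU": 0.309541,
   "GA": 2.019626,
   "GC": -1.334706,
   "GG": 0.8984,
   "GU": 1.538144,
   "UA": 0.540814,
   "UC": -0.064133,
   "UG": -1.24688,
   "UU": -0.195153
  },
  "shift": {
   "AA": 0.880502,
   "AC": 1.075441,
   "AG": -1.046219,
   "AU": 0.719001,
   "CA": 0.186779,
   "CC": -1.383108,
   "CG": 1.917563,
   "CU": -0.817638,
   "GA": -1.313507,
   "GC": -0.97572,
   "GG": 0.000571,
   "GU": -0.21497,
   "UA": -0.625413,
   "UC": 1.600019,
   "UG": 0.492518,
   "UU": -0.495819
  },
  "slide": {
   "AA": 0.16483,
   "AC": -0.183116,
   "AG": 0.203882,
   "AU": 0.208772,
   "CA": 0.929633,
   "CC": -0.38446,
   "CG": -0.105746,
   "CU": 2.252935,
   "GA": -0.668407,
   "GC": -0.715552,
   "GG": -1.466942,
   "GU": 0.044028,
   "UA": 0.140114,
   "UC": 1.874506,
   "UG": -1.635534,
   "UU": -0.658944
  },
  "tilt": {
   "AA": 0.421513,
   "AC": -0.953447,
   "AG": -0.665115,
   "AU": 1.114744,
   "CA": -0.558323,
   "CC": -1.473768,
   "CG": -1.358822,
   "CU": -0.187682,
   "GA": -0.034391,
   "GC": -0.362175,
   "GG": 0.286321,
   "GU": 2.153394,
   "UA": 0.806744,
   "UC": -0.89848,
   "UG": 0.115765,
   "UU": 1.593723
  },
  "twist": {
   "AA": 0.040971,
   "AC": -0.34545,
   "AG": 0.521387,
   "AU": -0.495085,
   "CA": -0.028456,
   "CC": -0.71614,
   "CG": -0.228966,
   "CU": -0.798948,
   "GA": -0.19146,
   "GC": -0.417084,
   "GG": 0.948642,
   "GU": 1.672937,
   "UA": 1.82357,
   "UC": 1.043504,
   "UG": -2.371591,
   "UU": -0.457831
  }
 }
}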