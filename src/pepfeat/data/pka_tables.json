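{
 "default": "lehninger",
 "tables": {
  "lehninger": {
   "n_terminus": 9.69,
   "c_terminus": 2.34,
   "acidic_sidechains": {
    "D": 3.65,
    "E": 4.25,
    "C": 8.18,
    "Y": 10.07
   },
   "basic_sidechains": {
    "H": 6.0,
    "K": 10.53,
    "R": 12.48
   },
   "ptm_acidic_groups": {
    "p": [
     1.2,
     6.5
    ]
   },
   "ptm_removes_sidechain": {
    "K[ac]": true
   }
  },
  "sillero": {
   "n_terminus": 8.2,
   "c_terminus": 3.2,
   "acidic_sidechains": {
    "D": 4.0,
    "E": 4.5,
    "C": 9.0,
    "Y": 10.0
   },
   "basic_sidechains": {
    "H": 6.4,
    "K": 10.4,
    "R": 12.0
   },
   "ptm_acidic_groups": {
    "p": [
     1.2,
     6.5
    ]
   },
   "ptm_removes_sidechain": {
    "K[ac]": true
   }
  }
 }
}
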