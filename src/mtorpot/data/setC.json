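{
 "weights": {
  "1": 0.0,
  "2": 1.0
 },
 "psi_deg": {
  "GG": -31.6,
  "GA": -35.1,
  "GP": -27.2,
  "AG": -30.7,
  "AA": -33.4,
  "AP": -11.1,
  "PG": -35.7,
  "PA": -31.2,
  "PP": -32.1
 },
 "m_max": 20,
 "name": "setC"
}
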