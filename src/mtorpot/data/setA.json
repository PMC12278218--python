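{
 "weights": {
  "1": 1.0,
  "2": 0.0
 },
 "psi_deg": {
  "GG": -12.4,
  "GA": -8.4,
  "GP": -19.3,
  "AG": -36.3,
  "AA": -15.5,
  "AP": -58.2,
  "PG": -9.5,
  "PA": -3.4,
  "PP": -79.9
 },
 "m_max": 20,
 "name": "setA"
}
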