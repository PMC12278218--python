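{
 "weights": {
  "1": 0.6,
  "2": 0.4
 },
 "psi_deg": {
  "GG": -24.6,
  "GA": -26.2,
  "GP": 41.0,
  "AG": -31.5,
  "AA": -27.1,
  "AP": -99.0,
  "PG": 7.2,
  "PA": 13.5,
  "PP": -85.0
 },
 "m_max": 20,
 "name": "setB"
}
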