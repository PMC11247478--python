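{
 "name": "O2",
 "formula": "O2",
 "atoms": [
  [
   1,
   "O"
  ],
  [
   2,
   "O"
  ]
 ],
 "bonds": [
  [
   1,
   2,
   2,
   null
  ]
 ]
}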