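{
 "name": "B",
 "formula": "C26H34O4",
 "atoms": [
  [
   1,
   "O"
  ],
  [
   2,
   "C"
  ],
  [
   3,
   "C"
  ],
  [
   4,
   "C"
  ],
  [
   5,
   "C"
  ],
  [
   6,
   "C"
  ],
  [
   7,
   "C"
  ],
  [
   8,
   "C"
  ],
  [
   9,
   "C"
  ],
  [
   10,
   "C"
  ],
  [
   11,
   "C"
  ],
  [
   12,
   "C"
  ],
  [
   13,
   "O"
  ],
  [
   14,
   "C"
  ],
  [
   15,
   "C"
  ],
  [
   16,
   "C"
  ],
  [
   17,
   "C"
  ],
  [
   18,
   "C"
  ],
  [
   19,
   "C"
  ],
  [
   20,
   "C"
  ],
  [
   21,
   "C"
  ],
  [
   22,
   "O"
  ],
  [
   23,
   "C"
  ],
  [
   24,
   "C"
  ],
  [
   25,
   "C"
  ],
  [
   26,
   "C"
  ],
  [
   27,
   "C"
  ],
  [
   28,
   "C"
  ],
  [
   29,
   "C"
  ],
  [
   30,
   "O"
  ],
  [
   31,
   "H"
  ],
  [
   32,
   "H"
  ],
  [
   33,
   "H"
  ],
  [
   34,
   "H"
  ],
  [
   35,
   "H"
  ],
  [
   36,
   "H"
  ],
  [
   37,
   "H"
  ],
  [
   38,
   "H"
  ],
  [
   39,
   "H"
  ],
  [
   40,
   "H"
  ],
  [
   41,
   "H"
  ],
  [
   42,
   "H"
  ],
  [
   43,
   "H"
  ],
  [
   44,
   "H"
  ],
  [
   45,
   "H"
  ],
  [
   46,
   "H"
  ],
  [
   47,
   "H"
  ],
  [
   48,
   "H"
  ],
  [
   49,
   "H"
  ],
  [
   50,
   "H"
  ],
  [
   51,
   "H"
  ],
  [
   52,
   "H"
  ],
  [
   53,
   "H"
  ],
  [
   54,
   "H"
  ],
  [
   55,
   "H"
  ],
  [
   56,
   "H"
  ],
  [
   57,
   "H"
  ],
  [
   58,
   "H"
  ],
  [
   59,
   "H"
  ],
  [
   60,
   "H"
  ],
  [
   61,
   "H"
  ],
  [
   62,
   "H"
  ],
  [
   63,
   "H"
  ],
  [
   64,
   "H"
  ]
 ],
 "bonds": [
  [
   1,
   2,
   1,
   "4B"
  ],
  [
   2,
   3,
   1,
   null
  ],
  [
   3,
   4,
   2,
   null
  ],
  [
   4,
   5,
   1,
   null
  ],
  [
   5,
   6,
   2,
   null
  ],
  [
   6,
   7,
   1,
   null
  ],
  [
   7,
   8,
   1,
   null
  ],
  [
   8,
   9,
   1,
   null
  ],
  [
   8,
   10,
   1,
   null
  ],
  [
   8,
   11,
   1,
   null
  ],
  [
   7,
   12,
   2,
   null
  ],
  [
   12,
   13,
   1,
   "3B"
  ],
  [
   12,
   14,
   1,
   null
  ],
  [
   14,
   15,
   2,
   null
  ],
  [
   14,
   16,
   1,
   null
  ],
  [
   16,
   17,
   2,
   null
  ],
  [
   17,
   18,
   1,
   null
  ],
  [
   18,
   19,
   1,
   null
  ],
  [
   19,
   20,
   2,
   null
  ],
  [
   20,
   21,
   1,
   null
  ],
  [
   21,
   22,
   1,
   "4B'"
  ],
  [
   18,
   23,
   2,
   null
  ],
  [
   23,
   24,
   1,
   null
  ],
  [
   24,
   25,
   1,
   null
  ],
  [
   25,
   26,
   1,
   null
  ],
  [
   25,
   27,
   1,
   null
  ],
  [
   25,
   28,
   1,
   null
  ],
  [
   24,
   29,
   2,
   null
  ],
  [
   29,
   30,
   1,
   "3B'"
  ],
  [
   5,
   15,
   1,
   null
  ],
  [
   16,
   29,
   1,
   null
  ],
  [
   1,
   31,
   1,
   "2B"
  ],
  [
   2,
   32,
   1,
   null
  ],
  [
   2,
   33,
   1,
   null
  ],
  [
   3,
   34,
   1,
   null
  ],
  [
   4,
   35,
   1,
   null
  ],
  [
   6,
   36,
   1,
   null
  ],
  [
   9,
   37,
   1,
   null
  ],
  [
   9,
   38,
   1,
   null
  ],
  [
   9,
   39,
   1,
   null
  ],
  [
   10,
   40,
   1,
   null
  ],
  [
   10,
   41,
   1,
   null
  ],
  [
   10,
   42,
   1,
   null
  ],
  [
   11,
   43,
   1,
   null
  ],
  [
   11,
   44,
   1,
   null
  ],
  [
   11,
   45,
   1,
   null
  ],
  [
   13,
   46,
   1,
   "1B"
  ],
  [
   15,
   47,
   1,
   null
  ],
  [
   17,
   48,
   1,
   null
  ],
  [
   19,
   49,
   1,
   null
  ],
  [
   20,
   50,
   1,
   null
  ],
  [
   21,
   51,
   1,
   null
  ],
  [
   21,
   52,
   1,
   null
  ],
  [
   22,
   53,
   1,
   "2B'"
  ],
  [
   23,
   54,
   1,
   null
  ],
  [
   26,
   55,
   1,
   null
  ],
  [
   26,
   56,
   1,
   null
  ],
  [
   26,
   57,
   1,
   null
  ],
  [
   27,
   58,
   1,
   null
  ],
  [
   27,
   59,
   1,
   null
  ],
  [
   27,
   60,
   1,
   null
  ],
  [
   28,
   61,
   1,
   null
  ],
  [
   28,
   62,
   1,
   null
  ],
  [
   28,
   63,
   1,
   null
  ],
  [
   30,
   64,
   1,
   "1B'"
  ]
 ]
}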