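{
 "name": "A",
 "formula": "C19H30O3",
 "atoms": [
  [
   1,
   "C"
  ],
  [
   2,
   "C"
  ],
  [
   3,
   "O"
  ],
  [
   4,
   "C"
  ],
  [
   5,
   "O"
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
   "C"
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
   "O"
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
   "C"
  ],
  [
   23,
   "H"
  ],
  [
   24,
   "H"
  ],
  [
   25,
   "H"
  ],
  [
   26,
   "H"
  ],
  [
   27,
   "H"
  ],
  [
   28,
   "H"
  ],
  [
   29,
   "H"
  ],
  [
   30,
   "H"
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
  ]
 ],
 "bonds": [
  [
   1,
   2,
   1,
   null
  ],
  [
   2,
   3,
   1,
   "4A"
  ],
  [
   3,
   4,
   1,
   "3A"
  ],
  [
   4,
   5,
   2,
   null
  ],
  [
   4,
   6,
   1,
   "2A"
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
   2,
   null
  ],
  [
   9,
   10,
   1,
   null
  ],
  [
   10,
   11,
   1,
   null
  ],
  [
   11,
   12,
   1,
   null
  ],
  [
   11,
   13,
   1,
   null
  ],
  [
   11,
   14,
   1,
   null
  ],
  [
   10,
   15,
   2,
   null
  ],
  [
   15,
   16,
   1,
   null
  ],
  [
   15,
   17,
   1,
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
   18,
   20,
   1,
   null
  ],
  [
   18,
   21,
   1,
   null
  ],
  [
   17,
   22,
   2,
   null
  ],
  [
   8,
   22,
   1,
   null
  ],
  [
   1,
   23,
   1,
   null
  ],
  [
   1,
   24,
   1,
   null
  ],
  [
   1,
   25,
   1,
   null
  ],
  [
   2,
   26,
   1,
   null
  ],
  [
   2,
   27,
   1,
   null
  ],
  [
   6,
   28,
   1,
   null
  ],
  [
   6,
   29,
   1,
   null
  ],
  [
   7,
   30,
   1,
   null
  ],
  [
   7,
   31,
   1,
   null
  ],
  [
   9,
   32,
   1,
   null
  ],
  [
   12,
   33,
   1,
   null
  ],
  [
   12,
   34,
   1,
   null
  ],
  [
   12,
   35,
   1,
   null
  ],
  [
   13,
   36,
   1,
   null
  ],
  [
   13,
   37,
   1,
   null
  ],
  [
   13,
   38,
   1,
   null
  ],
  [
   14,
   39,
   1,
   null
  ],
  [
   14,
   40,
   1,
   null
  ],
  [
   14,
   41,
   1,
   null
  ],
  [
   16,
   42,
   1,
   "1A"
  ],
  [
   19,
   43,
   1,
   null
  ],
  [
   19,
   44,
   1,
   null
  ],
  [
   19,
   45,
   1,
   null
  ],
  [
   20,
   46,
   1,
   null
  ],
  [
   20,
   47,
   1,
   null
  ],
  [
   20,
   48,
   1,
   null
  ],
  [
   21,
   49,
   1,
   null
  ],
  [
   21,
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
   22,
   52,
   1,
   null
  ]
 ]
}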