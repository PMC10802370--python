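{
 "sources": {
  "S1": [
   0,
   3.732050807568877
  ],
  "S2": [
   4,
   3.732050807568877
  ],
  "S3": [
   8,
   3.732050807568877
  ],
  "S4": [
   12,
   3.732050807568877
  ],
  "S5": [
   3,
   2.0
  ],
  "S6": [
   7,
   2.0
  ],
  "S7": [
   11,
   2.0
  ],
  "S8": [
   0,
   -3.732050807568877
  ],
  "S9": [
   4,
   -3.732050807568877
  ],
  "S10": [
   8,
   -3.732050807568877
  ],
  "S11": [
   12,
   -3.732050807568877
  ],
  "S12": [
   3,
   -2.0
  ],
  "S13": [
   7,
   -2.0
  ],
  "S14": [
   11,
   -2.0
  ]
 },
 "detectors": {
  "D1": [
   2,
   3.732050807568877
  ],
  "D2": [
   6,
   3.732050807568877
  ],
  "D3": [
   10,
   3.732050807568877
  ],
  "D4": [
   1,
   2.0
  ],
  "D5": [
   5,
   2.0
  ],
  "D6": [
   9,
   2.0
  ],
  "D7": [
   2,
   -3.732050807568877
  ],
  "D8": [
   6,
   -3.732050807568877
  ],
  "D9": [
   10,
   -3.732050807568877
  ],
  "D10": [
   1,
   -2.0
  ],
  "D11": [
   5,
   -2.0
  ],
  "D12": [
   9,
   -2.0
  ]
 },
 "channels": [
  {
   "index": 1,
   "source": "S1",
   "detector": "D4"
  },
  {
   "index": 2,
   "source": "S1",
   "detector": "D1"
  },
  {
   "index": 3,
   "source": "S5",
   "detector": "D4"
  },
  {
   "index": 4,
   "source": "S5",
   "detector": "D1"
  },
  {
   "index": 5,
   "source": "S2",
   "detector": "D1"
  },
  {
   "index": 6,
   "source": "S5",
   "detector": "D5"
  },
  {
   "index": 7,
   "source": "S2",
   "detector": "D5"
  },
  {
   "index": 8,
   "source": "S2",
   "detector": "D2"
  },
  {
   "index": 9,
   "source": "S6",
   "detector": "D5"
  },
  {
   "index": 10,
   "source": "S6",
   "detector": "D2"
  },
  {
   "index": 11,
   "source": "S3",
   "detector": "D2"
  },
  {
   "index": 12,
   "source": "S6",
   "detector": "D6"
  },
  {
   "index": 13,
   "source": "S3",
   "detector": "D6"
  },
  {
   "index": 14,
   "source": "S3",
   "detector": "D3"
  },
  {
   "index": 15,
   "source": "S7",
   "detector": "D6"
  },
  {
   "index": 16,
   "source": "S7",
   "detector": "D3"
  },
  {
   "index": 17,
   "source": "S4",
   "detector": "D3"
  },
  {
   "index": 18,
   "source": "S8",
   "detector": "D10"
  },
  {
   "index": 19,
   "source": "S8",
   "detector": "D7"
  },
  {
   "index": 20,
   "source": "S12",
   "detector": "D10"
  },
  {
   "index": 21,
   "source": "S12",
   "detector": "D7"
  },
  {
   "index": 22,
   "source": "S9",
   "detector": "D7"
  },
  {
   "index": 23,
   "source": "S12",
   "detector": "D11"
  },
  {
   "index": 24,
   "source": "S9",
   "detector": "D11"
  },
  {
   "index": 25,
   "source": "S9",
   "detector": "D8"
  },
  {
   "index": 26,
   "source": "S13",
   "detector": "D11"
  },
  {
   "index": 27,
   "source": "S13",
   "detector": "D8"
  },
  {
   "index": 28,
   "source": "S10",
   "detector": "D8"
  },
  {
   "index": 29,
   "source": "S13",
   "detector": "D12"
  },
  {
   "index": 30,
   "source": "S10",
   "detector": "D12"
  },
  {
   "index": 31,
   "source": "S10",
   "detector": "D9"
  },
  {
   "index": 32,
   "source": "S14",
   "detector": "D12"
  },
  {
   "index": 33,
   "source": "S14",
   "detector": "D9"
  },
  {
   "index": 34,
   "source": "S11",
   "detector": "D9"
  }
 ],
 "separation_cm": 2.0,
 "wavelengths_nm": [
  780.0,
  850.0
 ],
 "sampling_rate_hz": 10.0,
 "section_of_channel": {
  "1": "L-front",
  "2": "L-front",
  "3": "L-front",
  "4": "L-front",
  "5": "L-front",
  "6": "L-front",
  "7": "L-middle",
  "8": "L-middle",
  "9": "L-middle",
  "10": "L-middle",
  "11": "L-middle",
  "12": "L-middle",
  "13": "L-back",
  "14": "L-back",
  "15": "L-back",
  "16": "L-back",
  "17": "L-back",
  "18": "R-front",
  "19": "R-front",
  "20": "R-front",
  "21": "R-front",
  "22": "R-front",
  "23": "R-front",
  "24": "R-middle",
  "25": "R-middle",
  "26": "R-middle",
  "27": "R-middle",
  "28": "R-middle",
  "29": "R-middle",
  "30": "R-back",
  "31": "R-back",
  "32": "R-back",
  "33": "R-back",
  "34": "R-back"
 },
 "chains": {
  "L": [
   1,
   2,
   3,
   4,
   5,
   6,
   7,
   8,
   9,
   10,
   11,
   12,
   13,
   14,
   15,
   16,
   17
  ],
  "R": [
   18,
   19,
   20,
   21,
   22,
   23,
   24,
   25,
   26,
   27,
   28,
   29,
   30,
   31,
   32,
   33,
   34
  ]
 }
}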