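{
 "version": 1,
 "materials": [
  {
   "id": 0,
   "name": "air",
   "density": 0.00121,
   "composition": {
    "C": 0.000124,
    "N": 0.755268,
    "O": 0.231781,
    "Ar": 0.012827
   }
  },
  {
   "id": 1,
   "name": "lung",
   "density": 0.26,
   "composition": {
    "H": 0.103,
    "C": 0.105,
    "N": 0.031,
    "O": 0.749,
    "Na": 0.002,
    "P": 0.002,
    "S": 0.003,
    "Cl": 0.003,
    "K": 0.002
   }
  },
  {
   "id": 2,
   "name": "adipose",
   "density": 0.95,
   "composition": {
    "H": 0.114,
    "C": 0.598,
    "N": 0.007,
    "O": 0.278,
    "Na": 0.001,
    "S": 0.001,
    "Cl": 0.001
   }
  },
  {
   "id": 3,
   "name": "soft_tissue",
   "density": 1.04,
   "composition": {
    "H": 0.102,
    "C": 0.143,
    "N": 0.034,
    "O": 0.708,
    "Na": 0.002,
    "P": 0.003,
    "S": 0.003,
    "Cl": 0.002,
    "K": 0.003
   }
  },
  {
   "id": 4,
   "name": "transitional",
   "density": 1.1,
   "composition": {
    "C": 0.14381818181818182,
    "Ca": 0.015340909090909106,
    "Cl": 0.0018636363636363635,
    "H": 0.09736363636363635,
    "K": 0.0027954545454545454,
    "Mg": 0.0001363636363636365,
    "N": 0.034545454545454546,
    "Na": 0.0019318181818181817,
    "O": 0.6893863636363635,
    "P": 0.009818181818181823,
    "S": 0.003
   }
  },
  {
   "id": 5,
   "name": "bone_1",
   "density": 1.18,
   "composition": {
    "C": 0.1449090909090909,
    "Ca": 0.035795454545454526,
    "Cl": 0.0016818181818181821,
    "H": 0.09118181818181818,
    "K": 0.0025227272727272733,
    "Mg": 0.00031818181818181804,
    "N": 0.035272727272727275,
    "Na": 0.0018409090909090912,
    "O": 0.6645681818181819,
    "P": 0.0189090909090909,
    "S": 0.003
   }
  },
  {
   "id": 6,
   "name": "bone_2",
   "density": 1.28,
   "composition": {
    "C": 0.14627272727272728,
    "Ca": 0.06136363636363637,
    "Cl": 0.0014545454545454547,
    "H": 0.08345454545454546,
    "K": 0.002181818181818182,
    "Mg": 0.0005454545454545456,
    "N": 0.03618181818181819,
    "Na": 0.0017272727272727275,
    "O": 0.6335454545454545,
    "P": 0.030272727272727274,
    "S": 0.003
   }
  },
  {
   "id": 7,
   "name": "bone_3",
   "density": 1.4,
   "composition": {
    "C": 0.14790909090909093,
    "Ca": 0.09204545454545453,
    "Cl": 0.001181818181818182,
    "H": 0.0741818181818182,
    "K": 0.0017727272727272733,
    "Mg": 0.000818181818181818,
    "N": 0.03727272727272728,
    "Na": 0.0015909090909090912,
    "O": 0.5963181818181819,
    "P": 0.0439090909090909,
    "S": 0.003
   }
  },
  {
   "id": 8,
   "name": "bone_4",
   "density": 1.53,
   "composition": {
    "C": 0.1496818181818182,
    "Ca": 0.12528409090909093,
    "Cl": 0.0008863636363636363,
    "H": 0.06413636363636363,
    "K": 0.0013295454545454543,
    "Mg": 0.0011136363636363637,
    "N": 0.038454545454545457,
    "Na": 0.0014431818181818183,
    "O": 0.5559886363636364,
    "P": 0.05868181818181818,
    "S": 0.003
   }
  },
  {
   "id": 9,
   "name": "bone_5",
   "density": 1.66,
   "composition": {
    "C": 0.15145454545454548,
    "Ca": 0.1585227272727273,
    "Cl": 0.0005909090909090912,
    "H": 0.0540909090909091,
    "K": 0.0008863636363636367,
    "Mg": 0.001409090909090909,
    "N": 0.03963636363636364,
    "Na": 0.0012954545454545456,
    "O": 0.515659090909091,
    "P": 0.07345454545454547,
    "S": 0.0030000000000000005
   }
  },
  {
   "id": 10,
   "name": "bone_6",
   "density": 1.79,
   "composition": {
    "C": 0.1532272727272727,
    "Ca": 0.19176136363636367,
    "Cl": 0.0002954545454545452,
    "H": 0.04404545454545454,
    "K": 0.00044318181818181777,
    "Mg": 0.001704545454545455,
    "N": 0.04081818181818182,
    "Na": 0.0011477272727272727,
    "O": 0.4753295454545454,
    "P": 0.08822727272727274,
    "S": 0.003
   }
  },
  {
   "id": 11,
   "name": "bone_7",
   "density": 1.92,
   "composition": {
    "C": 0.155,
    "Ca": 0.225,
    "H": 0.034,
    "Mg": 0.002,
    "N": 0.042,
    "Na": 0.001,
    "O": 0.435,
    "P": 0.103,
    "S": 0.003
   }
  },
  {
   "id": 12,
   "name": "bone_8",
   "density": 2.1,
   "composition": {
    "C": 0.155,
    "Ca": 0.225,
    "H": 0.034,
    "Mg": 0.002,
    "N": 0.042,
    "Na": 0.001,
    "O": 0.435,
    "P": 0.103,
    "S": 0.003
   }
  }
 ],
 "hu_breakpoints": [
  [
   -1024.0,
   0.00121
  ],
  [
   -1000.0,
   0.00121
  ],
  [
   -100.0,
   0.93
  ],
  [
   0.0,
   1.0
  ],
  [
   100.0,
   1.14
  ],
  [
   1600.0,
   2.0
  ],
  [
   3000.0,
   2.8
  ]
 ],
 "density_edges": [
  0.05,
  0.6,
  0.995,
  1.07,
  1.1400000000000001,
  1.23,
  1.3399999999999999,
  1.4649999999999999,
  1.595,
  1.725,
  1.855,
  2.01
 ]
}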