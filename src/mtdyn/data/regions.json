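{
 "regions": [
  {
   "name": "A_CAHA",
   "residue_type": "A",
   "c_atom": "CA",
   "h_atom": "HA",
   "h_range": [
    3.38,
    5.14
   ],
   "c_range": [
    49.2,
    57.2
   ]
  },
  {
   "name": "A_CBHB",
   "residue_type": "A",
   "c_atom": "CB",
   "h_atom": "HB",
   "h_range": [
    0.83,
    1.87
   ],
   "c_range": [
    15.2,
    22.8
   ]
  },
  {
   "name": "S_CBHB",
   "residue_type": "S",
   "c_atom": "CB",
   "h_atom": "HB",
   "h_range": [
    3.35,
    4.39
   ],
   "c_range": [
    60.8,
    66.8
   ]
  },
  {
   "name": "V_CGHG",
   "residue_type": "V",
   "c_atom": "CG",
   "h_atom": "HG",
   "h_range": [
    0.27,
    1.35
   ],
   "c_range": [
    18.4,
    24.4
   ]
  },
  {
   "name": "L_CBHB",
   "residue_type": "L",
   "c_atom": "CB",
   "h_atom": "HB",
   "h_range": [
    0.94,
    2.3
   ],
   "c_range": [
    38.5,
    46.1
   ]
  },
  {
   "name": "L_CDHD",
   "residue_type": "L",
   "c_atom": "CD",
   "h_atom": "HD",
   "h_range": [
    0.19,
    1.31
   ],
   "c_range": [
    21.4,
    27.8
   ]
  },
  {
   "name": "R_CDHD",
   "residue_type": "R",
   "c_atom": "CD",
   "h_atom": "HD",
   "h_range": [
    2.64,
    3.6
   ],
   "c_range": [
    41.4,
    45.0
   ]
  },
  {
   "name": "I_CG2HG2",
   "residue_type": "I",
   "c_atom": "CG2",
   "h_atom": "HG2",
   "h_range": [
    0.24,
    1.32
   ],
   "c_range": [
    14.7,
    20.3
   ]
  },
  {
   "name": "T_CBHB",
   "residue_type": "T",
   "c_atom": "CB",
   "h_atom": "HB",
   "h_range": [
    3.5,
    4.82
   ],
   "c_range": [
    66.5,
    72.9
   ]
  },
  {
   "name": "N_CBHB",
   "residue_type": "N",
   "c_atom": "CB",
   "h_atom": "HB",
   "h_range": [
    2.15,
    3.47
   ],
   "c_range": [
    35.1,
    42.3
   ]
  },
  {
   "name": "E_CAHA",
   "residue_type": "E",
   "c_atom": "CA",
   "h_atom": "HA",
   "h_range": [
    3.43,
    5.07
   ],
   "c_range": [
    53.1,
    61.5
   ]
  },
  {
   "name": "V_CAHA",
   "residue_type": "V",
   "c_atom": "CA",
   "h_atom": "HA",
   "h_range": [
    3.01,
    5.33
   ],
   "c_range": [
    56.7,
    68.3
   ]
  }
 ],
 "note": "rectangles = BMRB mean +/- 2 sd"
}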