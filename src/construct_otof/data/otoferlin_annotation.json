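{
 "_comment": "Otoferlin (UniProt Q9HC10 long isoform, 1979 aa) annotation layers. Domain and region coordinates are the published otoferlin C2-domain and intrinsically-disordered-region intervals. comp_bias and coiled_coil ship empty (coordinates are curated, not published with the model; supply your own config to populate them). The exon map is a SYNTHETIC near-uniform 46-interval partition of 1-1979 in protein coordinates; replace it with a transcript-derived map for real analyses.",
 "protein_length": 1979,
 "domains": [
  {
   "start": 1,
   "end": 98,
   "code": 1,
   "name": "C2-1"
  },
  {
   "start": 236,
   "end": 357,
   "code": 2,
   "name": "C2-2"
  },
  {
   "start": 400,
   "end": 531,
   "code": 3,
   "name": "C2-3"
  },
  {
   "start": 944,
   "end": 1069,
   "code": 4,
   "name": "C2-4"
  },
  {
   "start": 1115,
   "end": 1242,
   "code": 5,
   "name": "C2-5"
  },
  {
   "start": 1464,
   "end": 1593,
   "code": 6,
   "name": "C2-6"
  },
  {
   "start": 1714,
   "end": 1865,
   "code": 7,
   "name": "C2-7"
  }
 ],
 "regions": [
  {
   "start": 128,
   "end": 171,
   "code": 1,
   "name": "IDR-1"
  },
  {
   "start": 642,
   "end": 694,
   "code": 2,
   "name": "IDR-2"
  },
  {
   "start": 1299,
   "end": 1324,
   "code": 3,
   "name": "IDR-3"
  },
  {
   "start": 1343,
   "end": 1405,
   "code": 4,
   "name": "IDR-4"
  }
 ],
 "comp_bias": [],
 "coiled_coil": [],
 "exons": [
  {
   "start": 1,
   "end": 43,
   "code": 1,
   "name": "exon 1"
  },
  {
   "start": 44,
   "end": 86,
   "code": 2,
   "name": "exon 2"
  },
  {
   "start": 87,
   "end": 129,
   "code": 3,
   "name": "exon 3"
  },
  {
   "start": 130,
   "end": 172,
   "code": 4,
   "name": "exon 4"
  },
  {
   "start": 173,
   "end": 215,
   "code": 5,
   "name": "exon 5"
  },
  {
   "start": 216,
   "end": 258,
   "code": 6,
   "name": "exon 6"
  },
  {
   "start": 259,
   "end": 301,
   "code": 7,
   "name": "exon 7"
  },
  {
   "start": 302,
   "end": 344,
   "code": 8,
   "name": "exon 8"
  },
  {
   "start": 345,
   "end": 387,
   "code": 9,
   "name": "exon 9"
  },
  {
   "start": 388,
   "end": 430,
   "code": 10,
   "name": "exon 10"
  },
  {
   "start": 431,
   "end": 473,
   "code": 11,
   "name": "exon 11"
  },
  {
   "start": 474,
   "end": 516,
   "code": 12,
   "name": "exon 12"
  },
  {
   "start": 517,
   "end": 559,
   "code": 13,
   "name": "exon 13"
  },
  {
   "start": 560,
   "end": 602,
   "code": 14,
   "name": "exon 14"
  },
  {
   "start": 603,
   "end": 645,
   "code": 15,
   "name": "exon 15"
  },
  {
   "start": 646,
   "end": 688,
   "code": 16,
   "name": "exon 16"
  },
  {
   "start": 689,
   "end": 731,
   "code": 17,
   "name": "exon 17"
  },
  {
   "start": 732,
   "end": 774,
   "code": 18,
   "name": "exon 18"
  },
  {
   "start": 775,
   "end": 817,
   "code": 19,
   "name": "exon 19"
  },
  {
   "start": 818,
   "end": 860,
   "code": 20,
   "name": "exon 20"
  },
  {
   "start": 861,
   "end": 903,
   "code": 21,
   "name": "exon 21"
  },
  {
   "start": 904,
   "end": 946,
   "code": 22,
   "name": "exon 22"
  },
  {
   "start": 947,
   "end": 989,
   "code": 23,
   "name": "exon 23"
  },
  {
   "start": 990,
   "end": 1032,
   "code": 24,
   "name": "exon 24"
  },
  {
   "start": 1033,
   "end": 1075,
   "code": 25,
   "name": "exon 25"
  },
  {
   "start": 1076,
   "end": 1118,
   "code": 26,
   "name": "exon 26"
  },
  {
   "start": 1119,
   "end": 1161,
   "code": 27,
   "name": "exon 27"
  },
  {
   "start": 1162,
   "end": 1204,
   "code": 28,
   "name": "exon 28"
  },
  {
   "start": 1205,
   "end": 1247,
   "code": 29,
   "name": "exon 29"
  },
  {
   "start": 1248,
   "end": 1290,
   "code": 30,
   "name": "exon 30"
  },
  {
   "start": 1291,
   "end": 1333,
   "code": 31,
   "name": "exon 31"
  },
  {
   "start": 1334,
   "end": 1376,
   "code": 32,
   "name": "exon 32"
  },
  {
   "start": 1377,
   "end": 1419,
   "code": 33,
   "name": "exon 33"
  },
  {
   "start": 1420,
   "end": 1462,
   "code": 34,
   "name": "exon 34"
  },
  {
   "start": 1463,
   "end": 1505,
   "code": 35,
   "name": "exon 35"
  },
  {
   "start": 1506,
   "end": 1548,
   "code": 36,
   "name": "exon 36"
  },
  {
   "start": 1549,
   "end": 1591,
   "code": 37,
   "name": "exon 37"
  },
  {
   "start": 1592,
   "end": 1634,
   "code": 38,
   "name": "exon 38"
  },
  {
   "start": 1635,
   "end": 1677,
   "code": 39,
   "name": "exon 39"
  },
  {
   "start": 1678,
   "end": 1720,
   "code": 40,
   "name": "exon 40"
  },
  {
   "start": 1721,
   "end": 1763,
   "code": 41,
   "name": "exon 41"
  },
  {
   "start": 1764,
   "end": 1806,
   "code": 42,
   "name": "exon 42"
  },
  {
   "start": 1807,
   "end": 1849,
   "code": 43,
   "name": "exon 43"
  },
  {
   "start": 1850,
   "end": 1892,
   "code": 44,
   "name": "exon 44"
  },
  {
   "start": 1893,
   "end": 1935,
   "code": 45,
   "name": "exon 45"
  },
  {
   "start": 1936,
   "end": 1979,
   "code": 46,
   "name": "exon 46"
  }
 ]
}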