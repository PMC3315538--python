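{
 "chart": {
  "entries": {
   "acoustic_shadows": [
    {
     "level": 0,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 1,
     "lower": null,
     "points": -5,
     "upper": null
    }
   ],
   "age": [
    {
     "level": null,
     "lower": null,
     "points": 0,
     "upper": 40
    },
    {
     "level": null,
     "lower": 40,
     "points": 1,
     "upper": 60
    },
    {
     "level": null,
     "lower": 60,
     "points": 3,
     "upper": null
    }
   ],
   "ascites": [
    {
     "level": 0,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 1,
     "lower": null,
     "points": 4,
     "upper": null
    }
   ],
   "color_score": [
    {
     "level": 1,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 2,
     "lower": null,
     "points": 1,
     "upper": null
    },
    {
     "level": 3,
     "lower": null,
     "points": 3,
     "upper": null
    },
    {
     "level": 4,
     "lower": null,
     "points": 5,
     "upper": null
    }
   ],
   "douglas_fluid": [
    {
     "level": null,
     "lower": null,
     "points": 0,
     "upper": 10
    },
    {
     "level": null,
     "lower": 10,
     "points": 2,
     "upper": 20
    },
    {
     "level": null,
     "lower": 20,
     "points": 4,
     "upper": null
    }
   ],
   "irregular_wall": [
    {
     "level": 0,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 1,
     "lower": null,
     "points": 3,
     "upper": null
    }
   ],
   "lesion_diameter": [
    {
     "level": null,
     "lower": null,
     "points": 0,
     "upper": 40
    },
    {
     "level": null,
     "lower": 40,
     "points": 1,
     "upper": 75
    },
    {
     "level": null,
     "lower": 75,
     "points": 3,
     "upper": 95
    },
    {
     "level": null,
     "lower": 95,
     "points": 4,
     "upper": 140
    },
    {
     "level": null,
     "lower": 140,
     "points": 5,
     "upper": 200
    },
    {
     "level": null,
     "lower": 200,
     "points": 8,
     "upper": null
    }
   ],
   "papillation_flow": [
    {
     "level": 0,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 1,
     "lower": null,
     "points": 3,
     "upper": null
    }
   ],
   "papillations_gt3": [
    {
     "level": 0,
     "lower": null,
     "points": 0,
     "upper": null
    },
    {
     "level": 1,
     "lower": null,
     "points": 4,
     "upper": null
    }
   ],
   "solid_ratio": [
    {
     "level": null,
     "lower": null,
     "points": 0,
     "upper": 0.25
    },
    {
     "level": null,
     "lower": 0.25,
     "points": 4,
     "upper": 0.55
    },
    {
     "level": null,
     "lower": 0.55,
     "points": 7,
     "upper": 0.9
    },
    {
     "level": null,
     "lower": 0.9,
     "points": 8,
     "upper": null
    }
   ]
  },
  "kinds": {
   "acoustic_shadows": "binary",
   "age": "continuous",
   "ascites": "binary",
   "color_score": "categorical",
   "douglas_fluid": "continuous",
   "irregular_wall": "binary",
   "lesion_diameter": "continuous",
   "papillation_flow": "binary",
   "papillations_gt3": "binary",
   "solid_ratio": "continuous"
  },
  "metadata": {
   "source": "packaged adnexal-mass interval-coded score chart"
  },
  "units": {
   "acoustic_shadows": "",
   "age": "years",
   "ascites": "",
   "color_score": "",
   "douglas_fluid": "mm",
   "irregular_wall": "",
   "lesion_diameter": "mm",
   "papillation_flow": "",
   "papillations_gt3": "",
   "solid_ratio": ""
  },
  "variables": [
   "age",
   "lesion_diameter",
   "solid_ratio",
   "papillations_gt3",
   "papillation_flow",
   "irregular_wall",
   "acoustic_shadows",
   "color_score",
   "ascites",
   "douglas_fluid"
  ]
 },
 "risk_table": {
  "rows": [
   {
    "display": "<0.001",
    "hi": 1,
    "lo": -5,
    "risk": 0.001
   },
   {
    "display": "0.01",
    "hi": 4,
    "lo": 2,
    "risk": 0.01
   },
   {
    "display": "0.04",
    "hi": 5,
    "lo": 5,
    "risk": 0.04
   },
   {
    "display": "0.06",
    "hi": 9,
    "lo": 6,
    "risk": 0.06
   },
   {
    "display": "0.10",
    "hi": 11,
    "lo": 10,
    "risk": 0.1
   },
   {
    "display": "0.12",
    "hi": 12,
    "lo": 12,
    "risk": 0.12
   },
   {
    "display": "0.24",
    "hi": 13,
    "lo": 13,
    "risk": 0.24
   },
   {
    "display": "0.36",
    "hi": 14,
    "lo": 14,
    "risk": 0.36
   },
   {
    "display": "0.54",
    "hi": 15,
    "lo": 15,
    "risk": 0.54
   },
   {
    "display": "0.63",
    "hi": 17,
    "lo": 16,
    "risk": 0.63
   },
   {
    "display": "0.69",
    "hi": 19,
    "lo": 18,
    "risk": 0.69
   },
   {
    "display": "0.91",
    "hi": 23,
    "lo": 20,
    "risk": 0.91
   },
   {
    "display": "0.93",
    "hi": 25,
    "lo": 24,
    "risk": 0.93
   },
   {
    "display": "0.96",
    "hi": 27,
    "lo": 26,
    "risk": 0.96
   },
   {
    "display": "0.98",
    "hi": 30,
    "lo": 28,
    "risk": 0.98
   },
   {
    "display": ">0.99",
    "hi": 42,
    "lo": 31,
    "risk": 0.999
   }
  ]
 },
 "schema_version": 1,
 "worked_example": {
  "expected_risk": 0.96,
  "expected_score": 27,
  "patient": {
   "acoustic_shadows": 0,
   "age": 56,
   "ascites": 0,
   "color_score": 3,
   "douglas_fluid": 18,
   "irregular_wall": 1,
   "lesion_diameter": 133,
   "papillation_flow": 1,
   "papillations_gt3": 1,
   "solid_ratio": 0.74
  }
 }
}
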