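{
 "name": "ANZMUSC-RQIT",
 "version": "1.0",
 "scale": [
  0,
  1000
 ],
 "dimensions": [
  {
   "code": "A",
   "label": "Extent to which the question is important to patients and other health decision-makers",
   "levels": [
    {
     "code": "A1",
     "descriptor": "Not shown to be important to either patients or decision-makers",
     "utility": 0,
     "se": 6.8
    },
    {
     "code": "A2",
     "descriptor": "Shown to be important to health decision-makers but not patients",
     "utility": 17,
     "se": 5.5
    },
    {
     "code": "A3",
     "descriptor": "Shown to be important to patients but not decision-makers",
     "utility": 92,
     "se": 5.3
    },
    {
     "code": "A4",
     "descriptor": "Shown to be important to both patients and decision-makers",
     "utility": 198,
     "se": 7.3
    }
   ]
  },
  {
   "code": "B",
   "label": "That it addresses an area of high patient burden",
   "levels": [
    {
     "code": "B1",
     "descriptor": "Mild symptoms and little or no associated disability",
     "utility": 0,
     "se": 8.1
    },
    {
     "code": "B2",
     "descriptor": "Moderate symptoms and some disability",
     "utility": 150,
     "se": 6.6
    },
    {
     "code": "B3",
     "descriptor": "Significantly disabling, associated with mortality risk or no effective treatments available",
     "utility": 250,
     "se": 7.7
    }
   ]
  },
  {
   "code": "C",
   "label": "That it addresses an area of high social burden",
   "levels": [
    {
     "code": "C1",
     "descriptor": "Condition is rare (prevalence <0.1%)",
     "utility": 0,
     "se": 7.9
    },
    {
     "code": "C2",
     "descriptor": "Condition is somewhat common (0.1-1%)",
     "utility": 28,
     "se": 5.4
    },
    {
     "code": "C3",
     "descriptor": "Condition is common (1-10%)",
     "utility": 119,
     "se": 5.4
    },
    {
     "code": "C4",
     "descriptor": "Condition is highly prevalent (>10%)",
     "utility": 173,
     "se": 8.0
    }
   ]
  },
  {
   "code": "D",
   "label": "Potential reduction in patient and/or social burden due to (clinical or implementation) intervention",
   "levels": [
    {
     "code": "D1",
     "descriptor": "Symptomatic treatment only",
     "utility": 0,
     "se": 8.1
    },
    {
     "code": "D2",
     "descriptor": "Potential for intervention to treat both symptoms and underlying disease pathology",
     "utility": 166,
     "se": 6.4
    },
    {
     "code": "D3",
     "descriptor": "Potential for cure or fundamental alteration of disease course",
     "utility": 265,
     "se": 7.8
    }
   ]
  },
  {
   "code": "E",
   "label": "Extent to which the question addresses health equity",
   "levels": [
    {
     "code": "E1",
     "descriptor": "No information",
     "utility": 0,
     "se": 7.7
    },
    {
     "code": "E2",
     "descriptor": "Not relevant",
     "utility": 45,
     "se": 5.4
    },
    {
     "code": "E3",
     "descriptor": "Somewhat (may have some application to reduce health disparity)",
     "utility": 67,
     "se": 5.0
    },
    {
     "code": "E4",
     "descriptor": "Reducing health disparity is the focus",
     "utility": 114,
     "se": 8.3
    }
   ]
  }
 ],
 "correlations": {
  "codes": [
   "A1",
   "A2",
   "A3",
   "A4",
   "B1",
   "B2",
   "B3",
   "C1",
   "C2",
   "C3",
   "C4",
   "D1",
   "D2",
   "D3",
   "E1",
   "E2",
   "E3",
   "E4"
  ],
  "matrix": [
   [
    1.0,
    -0.073,
    -0.342,
    -0.62,
    0.487,
    -0.195,
    -0.345,
    0.555,
    0.102,
    -0.093,
    -0.554,
    0.391,
    -0.116,
    -0.311,
    0.539,
    0.261,
    -0.033,
    -0.653
   ],
   [
    -0.073,
    1.0,
    -0.351,
    -0.429,
    0.155,
    -0.089,
    -0.086,
    0.227,
    -0.048,
    -0.035,
    -0.168,
    0.17,
    -0.131,
    -0.068,
    0.198,
    -0.076,
    -0.13,
    -0.058
   ],
   [
    -0.342,
    -0.351,
    1.0,
    -0.147,
    -0.104,
    0.07,
    0.049,
    -0.108,
    -0.053,
    -0.029,
    0.162,
    -0.089,
    0.044,
    0.056,
    -0.119,
    -0.119,
    0.043,
    0.162
   ],
   [
    -0.62,
    -0.429,
    -0.147,
    1.0,
    -0.489,
    0.195,
    0.347,
    -0.604,
    -0.02,
    0.133,
    0.52,
    -0.423,
    0.173,
    0.298,
    -0.56,
    -0.098,
    0.097,
    0.528
   ],
   [
    0.487,
    0.155,
    -0.104,
    -0.489,
    1.0,
    -0.466,
    -0.651,
    0.453,
    0.039,
    -0.074,
    -0.424,
    0.414,
    -0.082,
    -0.363,
    0.46,
    0.151,
    -0.061,
    -0.49
   ],
   [
    -0.195,
    -0.089,
    0.07,
    0.195,
    -0.466,
    1.0,
    -0.368,
    -0.136,
    0.007,
    -0.008,
    0.134,
    -0.057,
    -0.122,
    0.16,
    -0.136,
    -0.031,
    -0.047,
    0.175
   ],
   [
    -0.345,
    -0.086,
    0.049,
    0.347,
    -0.651,
    -0.368,
    1.0,
    -0.36,
    -0.047,
    0.084,
    0.331,
    -0.386,
    0.19,
    0.244,
    -0.366,
    -0.131,
    0.104,
    0.364
   ],
   [
    0.555,
    0.227,
    -0.108,
    -0.604,
    0.453,
    -0.136,
    -0.36,
    1.0,
    -0.168,
    -0.269,
    -0.693,
    0.46,
    -0.079,
    -0.414,
    0.556,
    0.272,
    -0.117,
    -0.624
   ],
   [
    0.102,
    -0.048,
    -0.053,
    -0.02,
    0.039,
    0.007,
    -0.047,
    -0.168,
    1.0,
    -0.338,
    -0.279,
    0.034,
    -0.097,
    0.045,
    0.098,
    -0.107,
    0.107,
    -0.087
   ],
   [
    -0.093,
    -0.035,
    -0.029,
    0.133,
    -0.074,
    -0.008,
    0.084,
    -0.269,
    -0.338,
    1.0,
    -0.186,
    -0.026,
    -0.008,
    0.034,
    -0.038,
    -0.082,
    -0.077,
    0.135
   ],
   [
    -0.554,
    -0.168,
    0.162,
    0.52,
    -0.424,
    0.134,
    0.331,
    -0.693,
    -0.279,
    -0.186,
    1.0,
    -0.461,
    0.149,
    0.356,
    -0.59,
    -0.14,
    0.095,
    0.584
   ],
   [
    0.391,
    0.17,
    -0.089,
    -0.423,
    0.414,
    -0.057,
    -0.386,
    0.46,
    0.034,
    -0.026,
    -0.461,
    1.0,
    -0.446,
    -0.671,
    0.434,
    0.203,
    -0.119,
    -0.465
   ],
   [
    -0.116,
    -0.131,
    0.044,
    0.173,
    -0.082,
    -0.122,
    0.19,
    -0.079,
    -0.097,
    -0.008,
    0.149,
    -0.446,
    1.0,
    -0.364,
    -0.125,
    -0.039,
    0.004,
    0.139
   ],
   [
    -0.311,
    -0.068,
    0.056,
    0.298,
    -0.363,
    0.16,
    0.244,
    -0.414,
    0.045,
    0.034,
    0.356,
    -0.671,
    -0.364,
    1.0,
    -0.348,
    -0.178,
    0.12,
    0.368
   ],
   [
    0.539,
    0.198,
    -0.119,
    -0.56,
    0.46,
    -0.136,
    -0.366,
    0.556,
    0.098,
    -0.038,
    -0.59,
    0.434,
    -0.125,
    -0.348,
    1.0,
    -0.079,
    -0.321,
    -0.69
   ],
   [
    0.261,
    -0.076,
    -0.119,
    -0.098,
    0.151,
    -0.031,
    -0.131,
    0.272,
    -0.107,
    -0.082,
    -0.14,
    0.203,
    -0.039,
    -0.178,
    -0.079,
    1.0,
    -0.253,
    -0.42
   ],
   [
    -0.033,
    -0.13,
    0.043,
    0.097,
    -0.061,
    -0.047,
    0.104,
    -0.117,
    0.107,
    -0.077,
    0.095,
    -0.119,
    0.004,
    0.12,
    -0.321,
    -0.253,
    1.0,
    -0.139
   ],
   [
    -0.653,
    -0.058,
    0.162,
    0.528,
    -0.49,
    0.175,
    0.364,
    -0.624,
    -0.087,
    0.135,
    0.584,
    -0.465,
    0.139,
    0.368,
    -0.69,
    -0.42,
    -0.139,
    1.0
   ]
  ]
 }
}
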