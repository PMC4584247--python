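{
  "family": "published_multilinear",
  "description": "Published 23-wavelength multilinear TSS prediction model for mulberries (intercept + signed coefficients on reflectance, output in degrees Brix).",
  "intercept": 16.207,
  "wavelengths_nm": [960, 929, 814, 849, 432, 500, 877, 995, 903, 915, 831, 956, 967, 954, 923, 511, 454, 840, 835, 527, 509, 850, 883],
  "coefficients": [-0.191, -0.818, -1.717, -1.481, 0.007, 0.037, -1.291, -0.193, -1.112, -1.017, -1.606, -0.230, -0.168, -0.132, -0.924, 0.042, 0.023, -1.541, -1.574, 0.047, 0.040, -1.474, -1.252]
}
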