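{
  "version": "chemotype-curated-1.0",
  "magic_constant": 0.219,
  "corrections": {
    "biaryl_conjugation": 0.262
  },
  "compounds": {
    "C1": {
      "name": "3-{4-[5-(indol-1-yl)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 1], ["indol-1-yl", 1]],
      "corrections": []
    },
    "C2": {
      "name": "3-{4-[5-(biphenyl-2-yloxy)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 2], ["O_ar", 2], ["C6H5", 1]],
      "corrections": ["biaryl_conjugation"]
    },
    "C3": {
      "name": "3-{4-[5-(benzo-1,3-thiazolyl)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 1], ["benzo-1,3-thiazol-2-yl", 1]],
      "corrections": []
    },
    "C4": {
      "name": "3-{4-[5-(5-chloroindol-1-yl)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 1], ["5-chloroindol-1-yl", 1]],
      "corrections": []
    },
    "C5": {
      "name": "3-{4-[5-(5-methoxyindol-1-yl)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 1], ["5-methoxyindol-1-yl", 1]],
      "corrections": []
    },
    "C6": {
      "name": "3-{4-[5-(biphenyl-4-yloxy)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 2], ["O_ar", 2], ["C6H5", 1]],
      "corrections": ["biaryl_conjugation"]
    },
    "C7": {
      "name": "3-{4-[5-phenoxypentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 2], ["C6H5", 1]],
      "corrections": []
    },
    "C8": {
      "name": "3-{4-[5-(phenanthren-9-yloxy)pentoxy]benzyl}-4H-1,2,4-oxadiazol-5-one",
      "fragments": [["oxadiazol-5-on-3-yl", 1], ["CH2", 6], ["C6H4", 1], ["O_ar", 2], ["phenanthren-9-yl", 1]],
      "corrections": []
    }
  }
}
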