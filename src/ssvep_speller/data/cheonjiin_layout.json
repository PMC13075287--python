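{
  "name": "cheonjiin-4x4",
  "kind": "cheonjiin",
  "home": [0, 0],
  "comment": "4x4 grid, 14 keys (2 empty cells). Row 0 is the vowel-element row with DELETE; consonant keys follow the de facto Cheonjiin phone arrangement; doubled consonants are the third tap.",
  "grid": [
    [
      {"kind": "vowel", "taps": ["ㅣ"], "label": "ㅣ"},
      {"kind": "vowel", "taps": ["ㆍ"], "label": "ㆍ"},
      {"kind": "vowel", "taps": ["ㅡ"], "label": "ㅡ"},
      {"kind": "function", "taps": ["DELETE"], "label": "DEL"}
    ],
    [
      {"kind": "consonant", "taps": ["ㄱ", "ㅋ", "ㄲ"], "label": "ㄱㅋ"},
      {"kind": "consonant", "taps": ["ㄴ", "ㄹ"], "label": "ㄴㄹ"},
      {"kind": "consonant", "taps": ["ㄷ", "ㅌ", "ㄸ"], "label": "ㄷㅌ"},
      null
    ],
    [
      {"kind": "consonant", "taps": ["ㅂ", "ㅍ", "ㅃ"], "label": "ㅂㅍ"},
      {"kind": "consonant", "taps": ["ㅅ", "ㅎ", "ㅆ"], "label": "ㅅㅎ"},
      {"kind": "consonant", "taps": ["ㅈ", "ㅊ", "ㅉ"], "label": "ㅈㅊ"},
      null
    ],
    [
      {"kind": "consonant", "taps": ["ㅇ", "ㅁ"], "label": "ㅇㅁ"},
      {"kind": "function", "taps": ["SPACE"], "label": "SPC"},
      {"kind": "function", "taps": ["ENTER"], "label": "ENT"},
      {"kind": "function", "taps": ["PERIOD"], "label": "."}
    ]
  ]
}
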