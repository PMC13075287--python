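{
  "name": "qwerty-2beolsik-fixture",
  "kind": "direct",
  "home": [0, 0],
  "comment": "Synthetic comparison fixture: the standard Korean 2-beolsik QWERTY jamo arrangement flattened onto a cursor-navigable grid (doubled consonants and ㅒ/ㅖ as second taps, standing in for Shift). Used only for keystroke-economy comparisons, never for composition.",
  "grid": [
    [
      {"kind": "consonant", "taps": ["ㅂ", "ㅃ"], "label": "ㅂ"},
      {"kind": "consonant", "taps": ["ㅈ", "ㅉ"], "label": "ㅈ"},
      {"kind": "consonant", "taps": ["ㄷ", "ㄸ"], "label": "ㄷ"},
      {"kind": "consonant", "taps": ["ㄱ", "ㄲ"], "label": "ㄱ"},
      {"kind": "consonant", "taps": ["ㅅ", "ㅆ"], "label": "ㅅ"},
      {"kind": "vowel", "taps": ["ㅛ"], "label": "ㅛ"},
      {"kind": "vowel", "taps": ["ㅕ"], "label": "ㅕ"},
      {"kind": "vowel", "taps": ["ㅑ"], "label": "ㅑ"},
      {"kind": "vowel", "taps": ["ㅐ", "ㅒ"], "label": "ㅐ"},
      {"kind": "vowel", "taps": ["ㅔ", "ㅖ"], "label": "ㅔ"}
    ],
    [
      {"kind": "consonant", "taps": ["ㅁ"], "label": "ㅁ"},
      {"kind": "consonant", "taps": ["ㄴ"], "label": "ㄴ"},
      {"kind": "consonant", "taps": ["ㅇ"], "label": "ㅇ"},
      {"kind": "consonant", "taps": ["ㄹ"], "label": "ㄹ"},
      {"kind": "consonant", "taps": ["ㅎ"], "label": "ㅎ"},
      {"kind": "vowel", "taps": ["ㅗ"], "label": "ㅗ"},
      {"kind": "vowel", "taps": ["ㅓ"], "label": "ㅓ"},
      {"kind": "vowel", "taps": ["ㅏ"], "label": "ㅏ"},
      {"kind": "vowel", "taps": ["ㅣ"], "label": "ㅣ"},
      null
    ],
    [
      {"kind": "consonant", "taps": ["ㅋ"], "label": "ㅋ"},
      {"kind": "consonant", "taps": ["ㅌ"], "label": "ㅌ"},
      {"kind": "consonant", "taps": ["ㅊ"], "label": "ㅊ"},
      {"kind": "consonant", "taps": ["ㅍ"], "label": "ㅍ"},
      {"kind": "vowel", "taps": ["ㅠ"], "label": "ㅠ"},
      {"kind": "vowel", "taps": ["ㅜ"], "label": "ㅜ"},
      {"kind": "vowel", "taps": ["ㅡ"], "label": "ㅡ"},
      {"kind": "function", "taps": ["SPACE"], "label": "SPC"},
      {"kind": "function", "taps": ["ENTER"], "label": "ENT"},
      {"kind": "function", "taps": ["PERIOD"], "label": "."}
    ]
  ]
}
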