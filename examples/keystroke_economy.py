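"""Keystroke economy: Cheonjiin vs a QWERTY grid under cursor control.

Counts the cursor movements and SELECT presses needed to type Korean
phrases on the 14-key Cheonjiin grid versus a QWERTY (2-beolsik) jamo grid
navigated with the same four directional commands.  Movement and selection
counts are reported separately because published comparisons differ in
which they include.
"""

from ssvep_speller import default_layout, movement_cost, qwerty_layout

cj, qw = default_layout(), qwerty_layout()
for text in ["안녕하세요", "머리", "감사합니다"]:
    a = movement_cost(text, cj)
    b = movement_cost(text, qw)
    print(f"{text!r}:")
    print(f"  cheonjiin: {a['movements']:3d} movements + {a['selects']:3d} selects")
    print(f"  qwerty   : {b['movements']:3d} movements + {b['selects']:3d} selects")
print("\nThe compact Cheonjiin grid needs fewer cursor movements per phrase; "
      "it pays with extra multi-tap selections on consonant keys.")
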