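"""Phono-semantic verdicts for biomedical characters.

Loads the shipped demonstration table and runs the finals-matching check
on characters whose composition is known: disease characters built on the
sickness radical with a phonetic component (病, 痨, 痛), organ characters
on the meat radical (肝, 胸 yes; 胃, 脑 no), and 徒, whose phonetic
radical 土 only appears at nesting depth 2.
"""

from phonosem import load_chardb, demo_chars_path, phono_semantic_check

db = load_chardb(demo_chars_path(), strict=True)

print(f"{'char':<6}{'verdict':<9}{'phonetic radical':<18}{'final':<7}depth")
for char in "病痨痛肝胸胃心害脑徒":
    v = phono_semantic_check(db, char)
    print(f"{char:<5}{str(v.is_phono_semantic):<9}"
          f"{v.phonetic_radical or '-':<17}{v.matched_final or '-':<7}"
          f"{v.depth or '-'}")

v1 = phono_semantic_check(db, "徒", max_depth=1)
print(f"\n徒 at max_depth=1: {v1.is_phono_semantic} — its depth-1 components "
      "彳 (chì) and 走 (zǒu) share no final with tú; the match needs the "
      "nested component 土 (tǔ).")
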