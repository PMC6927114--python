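"""Pinyin segmentation into initial, final and tone.

The phono-semantic check compares syllables by their final only, so the
segmentation convention matters: y/w count as initials, which is what
makes tòng and yǒng share the final "ong".
"""

from phonosem import parse_pinyin, toneless

for raw in ["bìng", "bǐng", "tòng", "yǒng", "gān", "gàn", "xiōng",
            "ā", "zǒu", "bing4", "lv4"]:
    p = parse_pinyin(raw)
    print(f"{raw:>7} -> initial={p.initial or '∅':<3} final={p.final:<5} "
          f"tone={p.tone}  toneless key: {toneless(p)}")

print("\nshared finals drive detection: "
      f"tòng/yǒng -> {parse_pinyin('tòng').final} == {parse_pinyin('yǒng').final}")
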