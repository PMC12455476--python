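#!/usr/bin/env python
"""Characterize the packaged sequences: length, sticker fraction, blockiness.

Finding: the four LCDs cluster at aromatic fraction f_h ~ 0.14 while the YS
variants span f_h = 0.0-1.0 at fixed length n = 150; at fixed composition
f_h = 0.20 the variants span blockiness f_B from ~0.02 to ~0.98.
"""

from pathlib import Path

import pandas as pd

from condnet.sequences import (LCD_NAMES, blockiness, build_lcd,
                               hydrophobic_fraction, load_packaged_ys_variants)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rows = []
for name in LCD_NAMES:
    seq = build_lcd(name)
    rows.append({"name": name, "family": "LCD", "n": len(seq),
                 "f_h": hydrophobic_fraction(seq), "f_B": None})
for seq in load_packaged_ys_variants():
    m = blockiness(seq)
    rows.append({"name": seq.name, "family": "YS", "n": len(seq),
                 "f_h": m.f_h, "f_B": m.f_B})

df = pd.DataFrame(rows)
df.to_csv(OUT / "sequence_features.tsv", sep="\t", index=False)

lcd = df[df.family == "LCD"]
print(f"LCD lengths: {sorted(lcd.n.tolist())}; f_h = "
      f"{lcd.f_h.min():.3f}-{lcd.f_h.max():.3f} (mean {lcd.f_h.mean():.3f})")
fh20 = df[(df.family == "YS") & (df.f_h.round(2) == 0.20)]
print(f"YS variants at f_h = 0.20 span f_B = {fh20.f_B.min():.3f}-{fh20.f_B.max():.3f}")
print(f"wrote {OUT / 'sequence_features.tsv'}")
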