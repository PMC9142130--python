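"""Reproduce the published wheat vs tritordeum fold-ratios.

The package bundles the published motif-event counts for white wheat and
tritordeum flours (chymotrypsin and trypsin digestions). The two-flour
comparison recomputes the reported perfect-match fold-ratios — e.g. CD
epitopes 49/14 -> 3.5 and G12 22/4 -> 5.5 under chymotrypsin.
"""

from glutenscan import (
    MatchMode,
    MotifCategory,
    compare_flours,
    load_reference_counts,
)

for enzyme in ("chymotrypsin", "trypsin"):
    wheat = load_reference_counts(f"wheat_{enzyme}")
    trit = load_reference_counts(f"tritordeum_{enzyme}")
    comp = compare_flours(wheat, trit, MatchMode.PERFECT)
    print(f"\n{enzyme}, perfect match (wheat / tritordeum):")
    for cat in MotifCategory:
        w = wheat.get(cat, MatchMode.PERFECT)
        t = trit.get(cat, MatchMode.PERFECT)
        r = comp.ratios[cat]
        print(f"  {cat.value:<12} {w:>3} / {t:<3} -> {'NA' if r is None else r}")
print("\nNA marks a zero comparator count (undefined ratio, never a number)")
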