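"""Recommend a donor punch size for one DALK case.

A keratoconus patient with mean keratometry 62 D is to receive a 7.75-mm
trephination.  The script computes the arc of Descemet's membrane that the
trephine leaves on the recipient bed and the punch size that matches it.
"""

from dalksizer import recommend_punch

K = 62.0        # recipient mean keratometry, diopters
TREPHINE = 7.75  # trephine diameter, mm

rec = recommend_punch(K, TREPHINE)

print(f"Recipient keratometry:     {K:g} D")
print(f"Trephine diameter:         {TREPHINE:.2f} mm")
print(f"DM arc length (exact):     {rec.exact_size:.4f} mm")
print(f"Recommended punch (table): {rec.table_size:.2f} mm")
print(f"Nearest available punch:   {rec.snapped_size:.2f} mm ({rec.step:g}-mm steps)")
print()
print("The membrane left on the bed is longer than the trephine chord because")
print("the steep cornea is curved; the donor is punched flat, so the punch")
print("must match the arc, not the trephine, to avoid membrane folds.")
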