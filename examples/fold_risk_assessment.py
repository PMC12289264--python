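"""Check fold risk when trephine and punch are the same size.

Using equal trephine and punch sizes in a steep cornea undersizes the graft
relative to the retained Descemet's membrane — the configuration reported to
produce membrane folds.  The script quantifies the mismatch.
"""

from dalksizer import assess_mismatch

for punch in (7.75, 8.75):
    rep = assess_mismatch(keratometry=62.0, trephine=7.75, punch=punch)
    risk = "FOLD RISK" if rep.fold_risk else "safe"
    print(
        f"punch {rep.punch:.2f} mm vs DM arc {rep.dm_arc:.2f} mm: "
        f"mismatch {rep.mismatch:+.2f} mm -> {risk}"
    )

print()
print("A positive mismatch means the membrane is longer than the graft and")
print("must wrinkle under the sutured button; a negative mismatch (oversized")
print("graft) leaves the membrane stretched flat.")
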