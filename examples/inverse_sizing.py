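"""Inverse problem: which trephine fits a punch already in stock?

If only an 8.00-mm donor punch is available for a 65 D cornea, the script
finds the trephine diameter whose Descemet's-membrane arc equals exactly
8.00 mm, then verifies the round trip through the forward model.
"""

from dalksizer import dm_arc_length, trephine_for_punch

K = 65.0
PUNCH_IN_STOCK = 8.00

trephine = trephine_for_punch(K, PUNCH_IN_STOCK)
arc_back = dm_arc_length(K, trephine)

print(f"Cornea:            {K:g} D (radius {337.5 / K:.4f} mm)")
print(f"Punch in stock:    {PUNCH_IN_STOCK:.2f} mm")
print(f"Required trephine: {trephine:.4f} mm")
print(f"Round-trip arc:    {arc_back:.6f} mm (should equal the punch)")
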