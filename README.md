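# dalksizer

Donor punch sizing for deep anterior lamellar keratoplasty (DALK), for
corneal surgeons and ophthalmic researchers planning grafts in steep
(keratoconic) corneas.

## The problem

In DALK the trephine cuts a circular button out of the recipient cornea
while the Descemet's membrane (DM) underneath is preserved. On a steep
cornea the removed cap — and the DM left on the bed — is a curved arc that
is *longer* than the trephine's diameter. The donor cornea, by contrast, is
flattened under suction when punched, so the donor button's length equals
the punch diameter. Cutting donor and recipient with the same size therefore
undersizes the graft relative to the retained membrane, and the excess
membrane wrinkles into DM folds that degrade vision.

## The model

Treat the recipient cornea as a sphere. Keratometry K (diopters) gives the
radius of curvature through the standard keratometric index n = 1.3375:

    r = 337.5 / K          (r in mm, K in D)

The trephine diameter *a* is a chord of that sphere. Joining its endpoints
to the centre of curvature forms an isosceles triangle with equal sides
b = c = r, so the cosine rule gives the central (apex) angle:

    cos α = (b² + c² − a²) / 2bc = 1 − a² / 2r²

and the DM arc left on the bed is

    x = r·α  (α in radians)   ≡   2πr·(α/360)  (α in degrees).

The recommended donor punch size is x; since punches come in 0.25-mm steps,
the package also snaps x to the nearest available size (ties break upward,
because undersizing is the fold-forming direction). The inverse problem —
which trephine to use so that a punch already in stock fits exactly — is
solved in closed form as a = 2r·sin(x/2r).

## Worked example

A 62 D keratoconic cornea trephined at 7.75 mm
(`python examples/single_case_recommendation.py`):

```
Recipient keratometry:     62 D
Trephine diameter:         7.75 mm
DM arc length (exact):     8.6240 mm
Recommended punch (table): 8.62 mm
Nearest available punch:   8.50 mm (0.25-mm steps)
```

r = 337.5/62 ≈ 5.44 mm; the 7.75-mm chord subtends ≈ 1.584 rad, so the
membrane on the bed is 8.62 mm long — 0.87 mm longer than the trephine. A
7.75-mm punch (equal sizing) would leave that much membrane to fold; the
model calls for an ~8.6-mm graft instead.

The same numbers from the shell:

```sh
dalksizer calc --k 62 --trephine 7.75
dalksizer mismatch --k 62 --trephine 7.75 --punch 7.75   # fold risk: YES
dalksizer table --format markdown                        # the full grid
dalksizer validate                                       # regression check
```

`dalksizer table` regenerates the full lookup grid — curvatures 45–70 D in
1-D steps by trephine sizes 6.00–8.00 mm in 0.25-mm steps, 234 cells — and
`dalksizer validate` compares it cell-by-cell against the transcription of
the published table shipped with the package (`dalksizer.data`): 0 of 234
cells deviate at the strict 0.005-mm tolerance.

Other entry points: `examples/fold_risk_assessment.py` (mismatch sign and
fold risk), `examples/inverse_sizing.py` (trephine for an in-stock punch),
`examples/build_and_validate_table.py` (grid generation + validation from
Python).

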