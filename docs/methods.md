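# Methods

## Model and assumptions

The recipient cornea is modelled as a sphere of a single radius of
curvature r. This is the strongest assumption in the package: a real
(especially keratoconic) cornea is aspheric and astigmatic, and the model
collapses it to one number. Consequences:

- **Which K to use is the user's call.** Clinical keratometry reports a flat
  (K1) and steep (K2) meridian power and their mean (Km). The model takes a
  single K; the CLI's `--k-choice` flag records which reading was supplied
  but never picks one, because no principled single-sphere reduction of an
  astigmatic cornea exists within this geometry.
- **The trephine cut is a circle of the stated diameter on that sphere**,
  i.e. the trephine does not deform the recipient during the cut.
- **The donor is punched flat**, so donor button diameter = punch diameter.
  This is the asymmetry the whole model rests on: recipient tissue is
  measured along an arc, donor tissue along a chord.

Under these assumptions the Descemet's membrane retained on the recipient
bed after trephination is the circular arc subtended by the trephine chord:

    r = kindex / K,  cos α = 1 − a²/2r²,  x = r·α

with a the trephine diameter. The matching donor punch size is x. The
inverse map (trephine for a target punch) is a = 2r·sin(x/2r), defined for
x ≤ πr (no chord subtends more than a semicircular arc).

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `kindex` | D·mm | 337.5 | diopter→radius constant; 337.5 is the standard keratometric index n = 1.3375. Configurable for keratometers calibrated differently. |
| `step` | mm | 0.25 | punch/trephine availability granularity |
| `snap_policy` | — | nearest-up-on-tie | tie-break when the exact size is equidistant between steps |
| `risk_threshold` | mm | 0.0 | undersizing beyond this flags fold risk |

The default `kindex` was fixed by a brute-force fit: regenerating all 234
cells of the reference grid with each candidate constant (337.5, 337.0,
336.0, 334.375, 334.0, 333.0) and keeping the one with zero cells deviating
beyond 0.01 mm. Only 337.5 achieves this — in fact it reproduces every cell
exactly at 2 decimals — so it is locked in as the default while remaining a
parameter.

`risk_threshold` defaults to zero — any undersizing is flagged — because no
clinically established tolerance band for DM/graft mismatch exists; the
threshold is exposed rather than invented.

## Numerical choices

- **Angles** are computed and carried in radians; the degree form
  2πr(α/360) is the same quantity, not a second code path.
- **Apex angle** uses the cosine rule directly, `arccos(1 − a²/2r²)`, with
  the argument clamped to [−1, 1] to absorb the one-ulp excursion at
  a = 2r. The mathematically identical half-angle form `2·arcsin(a/2r)` is
  kept in the test suite as an independent oracle; the two agree to better
  than 1e−12 rad across the domain, and the cosine form's arc error at the
  flattest probed cornea (K = 0.001 D) is below 1e−7 mm, so no stabilised
  variant is needed.
- **Rounding** of table values is half-away-from-zero to 2 decimals
  (`round_half_away`), not Python's banker's rounding. The reference grid
  reproduces exactly under this rule, which is the package's evidence for
  it; the validator still offers a relaxed 0.01-mm tier in case a
  differently-rounded table is compared.
- **Snapping** operates on the exact (unrounded) arc length, not on the
  printed 2-decimal value, and resolves exact ties (to 1e−9 relative)
  upward by default: the harmful direction is the undersized graft, so a
  tie goes to the larger punch. `always-up` is available when any
  undersizing at all is unacceptable. Snapped values are exact multiples of
  `step`; snapping is idempotent.
- **Tolerances**: internal invariant checks use 1e−9 relative
  (`_constants.REL_TOL`); grid validation uses 0.005 mm strict / 0.01 mm
  relaxed per cell.

## Input guards

Only geometric impossibility is a hard error: a trephine wider than the
corneal sphere's diameter (a > 2r), a target punch beyond the semicircular
arc (x > πr), or non-positive inputs. Inputs outside the tabulated envelope
(45–70 D × 6.00–8.00 mm) — the domain over which the grid was validated —
compute normally but emit a `ClinicalRangeWarning`, with stronger wording
outside the plausible human range (20–90 D × 4–10 mm). Rationale: the
geometry is exact everywhere it is defined, but clinical validation is not.

## The reference grid

`dalksizer/data/reference_punch_table.csv` transcribes the published
26 × 9 lookup table verbatim, including two cells printed with a single
decimal ("7.6" at 47 D/7.25 mm, "7.8" at 57 D/7.25 mm), which are read as
trailing-zero-trimmed 2-decimal values and normalised on load.
`validate_against_reference` regenerates the grid and counts per-cell
deviations; at the strict 0.005-mm tolerance zero of 234 cells deviate, so
no printed cell is a transcription or rounding anomaly.

## What the tests do and do not show

The package contains no synthetic-data generator and no randomness in the
model: all inputs are scalar clinical parameters, and the test fixtures are
the published grid plus closed-form identities (oracle equivalence of the
two apex-angle forms over 10⁴ random chord/radius pairs, forward/inverse
round-trips at 1e−9 mm, monotonicity in both axes, the flat-cornea limit
x → a as K → 0). Passing tests therefore show that the geometry is
implemented exactly and reproduces the published table — they say nothing
about whether a single-sphere model is an adequate description of any
particular patient's cornea, which is a clinical question outside the
package's scope.

## Known limitations

- No aspheric or conic corneal model; no astigmatism handling beyond
  documenting which K the user chose.
- No modelling of corneal thickness, trephination depth, suture tension or
  postoperative refraction.
- The fold-risk flag is a geometric statement (membrane longer than graft),
  not a validated clinical risk score.
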