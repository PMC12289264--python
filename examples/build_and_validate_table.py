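"""Regenerate the punch-size lookup grid and check it against the packaged
reference transcription.

The grid covers recipient curvatures 45-70 D (1-D steps) by trephine sizes
6.00-8.00 mm (0.25-mm steps); every cell is the 2-decimal DM arc length,
i.e. the suggested donor punch size.
"""

from dalksizer import format_table, generate_table, validate_against_reference

table = generate_table()
report = validate_against_reference(table, tolerance=0.005)

print(f"grid: {table.shape[0]} curvatures x {table.shape[1]} trephine sizes "
      f"= {report.n_cells} cells")
print(f"cells deviating from the reference by > {report.tolerance} mm: "
      f"{report.n_mismatched}")
print(f"max |deviation|: {report.max_abs_dev:.4f} mm")
print()
print("first rows of the generated grid (csv):")
print("\n".join(format_table(table, "csv").splitlines()[:4]))
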