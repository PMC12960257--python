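"""Design a Dipid monomer for a target container diameter.

Solves the curvature-domain length for a 400-nm container, prints the
resulting cone angle and strand table summary, and exports the design.
"""

from dipid import generate_variant, solve_curvature_length
from dipid.io import strands_table

design = solve_curvature_length(400.0)
outer = design.face_strand("outer")
print(f"target 400 nm -> curvature domain nT = {outer.curvature_len} T")
print(f"cone angle alpha_naive = {design.cone_angle_naive:.2f} deg")
print(f"predicted diameter d_naive = {design.diameter_naive:.1f} nm")
# alpha is the wedge a monomer subtends in the shell; d_naive = 2 s_mid/alpha

table = strands_table(design)
print(table.groupby("face").size().rename("strands per face").to_string())

m = generate_variant("M")
print(f"\nM class: nT = {m.face_strand('outer').curvature_len}, "
      f"d_naive = {m.diameter_naive:.0f} nm (measured mean 396 nm)")
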