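"""Pore sizes in an ideal Dipid shell.

Builds a geodesic sphere of monomer centres at the assembly spacing and
measures every junction opening as a largest inscribed circle.
"""

from dipid import pore_census
from dipid.synth import make_shell

layout = make_shell("sphere", size=3, spacing=37.7)
reports, summary = pore_census(layout)
print(summary.round(2).to_string(index=False))
# trimeric pores: openings of the close-packed lattice; on the geodesic
# sphere the edge-length spread widens them relative to the flat lattice

holey = make_shell("sheet", size=9, length=9, n_vacancies=1, seed=4)
_, summary2 = pore_census(holey)
print("\nsheet with one vacancy:")
print(summary2.round(2).to_string(index=False))
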