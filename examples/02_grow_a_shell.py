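"""Grow one bead-spring shell and classify its morphology.

A cone angle of 10 degrees closes into a small spheroidal container;
the coordination census shows the twelve net five-fold disclinations
every closed triangulated shell must carry.
"""

from dipid import run_assembly
from dipid.assembly import GrowthParams
from dipid.mesh import ElasticParams

res = run_assembly(ElasticParams(theta0=10.0),
                   GrowthParams(seed=1, max_monomers=300))
r = res.report
print(f"classification: {r.classification}  (closed={r.closed})")
print(f"monomers: {r.n_monomers}")
print(f"d_major x d_minor: {r.d_major:.0f} x {r.d_minor:.0f} nm, "
      f"aspect a = {r.aspect_ratio:.2f}")
print(f"coordination census: {r.coordination_census}")
print(f"net disclination charge sum(6-c): {r.net_disclination_charge} "
      "(= 12 for any closed shell)")
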