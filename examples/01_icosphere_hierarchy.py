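"""Build the icosphere subdivision hierarchy and its pooling maps.

Each subdivision adds one node per unique edge (re-projected to the unit
sphere), quadrupling the triangle count; pooling runs the hierarchy in
reverse, averaging each parent node with its 1-ring children.
"""

from spherecnn import base_icosahedron, pooling_map, subdivide

mesh = base_icosahedron()
hierarchy = [mesh]
for _ in range(6):
    mesh = subdivide(mesh)
    hierarchy.append(mesh)

print("level  nodes  triangles  edges")
for m in hierarchy:
    print(f"{m.level:5d}  {m.n_nodes:5d}  {m.n_triangles:9d}  {len(m.edges()):6d}")

pm = pooling_map(hierarchy[2], hierarchy[1])
sizes = sorted({len(ch) for ch in pm.children})
print(f"\npooling 162 -> 42 nodes: child-set sizes {sizes}")
print("(6 = the 12 original icosahedron vertices keep degree 5; 7 = degree-6 nodes)")
print("midpoint nodes feed exactly", int(pm.multiplicity[42:].max()), "parents each")
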