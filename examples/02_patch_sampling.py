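"""Place 5x5 filter patches on the sphere and build the filter point matrix.

A planar 5x5 grid is mapped to the sphere at every node (azimuthal-
equidistant projection, x-axis along the local east direction), each filter
point snaps to its nearest mesh node, and gathering a surface map through
the resulting index table yields the N x 25 matrix I whose product with a
filter weight vector performs mesh convolution in one step.
"""

import numpy as np

from spherecnn import build_sampling_map, icosphere, rectangular_template, sample

mesh = icosphere(3)  # 642 nodes
spacing = mesh.mean_edge_angle()
template = rectangular_template(5, 5, spacing)
smap = build_sampling_map(template, mesh)

print(f"mesh: {mesh.n_nodes} nodes, mean 1-ring edge angle {spacing:.4f} rad")
print(f"sampling map: {smap.index.shape[0]} nodes x {smap.index.shape[1]} filter points")
print("point 0 of every patch is the node itself:",
      bool(np.all(smap.index[:, 0] == np.arange(mesh.n_nodes))))

# an indicator map lights up exactly the patches that sample node 100
v = np.zeros(mesh.n_nodes)
v[100] = 1.0
I = sample(smap, v)
touched = np.unique(np.nonzero(I.values[:, :, 0])[0])
print(f"node 100 is sampled by the patches of {len(touched)} nearby nodes")
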