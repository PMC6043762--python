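"""Two-class synthetic cohorts of thickness-like maps on the icosphere.

The generator emulates the structure of cortical-thickness group data: a
smooth subject-invariant baseline field in the 2-4 mm range (a low-order
combination of degree <= 2 spherical harmonics), a class-dependent mean
shift confined to one or more geodesic disc regions (with a cosine taper
over the outer 20% of each disc's radius), spatially correlated additive
Gaussian noise (iterated 1-ring smoothing of white noise, rescaled to the
requested SD), and a medial-wall-like invalid cap around the south pole of
each hemisphere channel.

It does not emulate cortical folding, sulcal patterns, hemispheric
asymmetries, or the covariance structure of real thickness maps; passing
tests demonstrate the correctness of the pipeline, not clinical accuracy.

Defaults define the reference study conditions used throughout the test
suite: 200 subjects per class on the level-3 icosphere (642 nodes), one
effect region of radius 0.5 rad with a 0.3 mm class shift, 0.1 mm noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .icosphere import IcosphereMesh, icosphere
from .transforms import SphericalRotation, rotation_index

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "rotated_cohort"]

# Direction of the default effect-region center: mid-latitude, away from
# both poles and the medial-wall cap.
_DEFAULT_CENTER_DIR = np.array([1.0, 1.0, 0.5])


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    effect_regions: list of (center_node, radius_rad, effect_mm); a center
    of None picks the mesh node nearest a fixed mid-latitude direction.
    """

    n_per_class: int = 200
    level: int = 3
    effect_regions: tuple = ((None, 0.5, 0.3),)
    baseline_mean: float = 3.0
    baseline_amplitude: float = 0.8
    noise_sd: float = 0.1
    smoothing_iters: int = 3
    medial_wall_radius: float = 0.3
    seed: int = 0


@dataclass
class Cohort:
    """Generated cohort: maps, labels, validity and ground truth.

    X : (S, N, 2) values (two hemisphere channels); y : (S,) labels 0/1;
    valid : (N, 2) bool; truth holds the per-node expected class difference
    and the effect-region membership used to verify saliency localization.
    """

    X: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    level: int
    mesh: IcosphereMesh
    truth: dict
    spec: CohortSpec = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def network_inputs(self) -> np.ndarray:
        """Per-subject demeaned inputs with invalid nodes zeroed.

        The demeaning mean is taken over valid nodes of both channels, one
        scalar per subject, mirroring the preprocessing of real maps.
        """
        mask = self.valid[None, :, :]
        means = np.array(
            [x[self.valid].mean() for x in self.X]
        )[:, None, None]
        return np.where(mask, self.X - means, 0.0)


def _harmonic_baseline(
    nodes: np.ndarray, mean: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth field in roughly [mean - amp, mean + amp] mm from real
    spherical harmonics of degree <= 2 (Cartesian polynomial basis)."""
    x, y, z = nodes.T
    basis = np.column_stack(
        [x, y, z, x * y, y * z, z * x, x * x - y * y, 3 * z * z - 1]
    )
    coef = rng.standard_normal(basis.shape[1])
    f = basis @ coef
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return mean + amplitude * f


def _region_taper(mesh: IcosphereMesh, center: int, radius: float) -> np.ndarray:
    """Geodesic-disc membership with a cosine taper on the outer 20%."""
    d = np.arccos(np.clip(mesh.nodes @ mesh.nodes[center], -1.0, 1.0))
    inner = 0.8 * radius
    t = np.zeros(mesh.n_nodes)
    t[d <= inner] = 1.0
    edge = (d > inner) & (d < radius)
    t[edge] = 0.5 * (1.0 + np.cos(np.pi * (d[edge] - inner) / (radius - inner)))
    return t


def _smooth_noise(
    shape: tuple, mesh: IcosphereMesh, iters: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially correlated noise: iterated 1-ring mean smoothing of white
    noise, rescaled per subject and channel to the requested SD."""
    import scipy.sparse as sp

    noise = rng.standard_normal(shape)  # (S, N, C)
    if iters > 0:
        nb = mesh.neighbors()
        rows, cols = [], []
        for i, v in enumerate(nb):
            rows.extend([i] * (len(v) + 1))
            cols.extend([i, *v])
        deg = np.array([len(v) + 1 for v in nb], dtype=np.float64)
        vals = np.concatenate([np.full(int(d), 1.0 / d) for d in deg])
        M = sp.csr_matrix(
            (vals, (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
        )
        s, n, c = shape
        flat = noise.transpose(1, 0, 2).reshape(n, s * c)
        for _ in range(iters):
            flat = M @ flat
        noise = flat.reshape(n, s, c).transpose(1, 0, 2)
    if sd > 0:
        stds = noise.std(axis=1, keepdims=True)
        stds[stds == 0] = 1.0
        noise = noise * (sd / stds)
    else:
        noise = np.zeros(shape)
    return noise


def generate_cohort(spec: CohortSpec, mesh: IcosphereMesh | None = None) -> Cohort:
    """Generate a labeled two-class cohort with known ground truth.

    Class 1 receives the regional effect added on top of the shared
    baseline; both hemisphere channels carry the effect, with independent
    noise. Bit-reproducible for a fixed seed.
    """
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mesh is None:
        mesh = icosphere(spec.level)
    rng = np.random.default_rng(spec.seed)
    n = mesh.n_nodes
    s = 2 * spec.n_per_class

    # medial-wall-like invalid cap around the south pole, per channel
    south = np.array([0.0, 0.0, -1.0])
    cap = np.arccos(np.clip(mesh.nodes @ south, -1, 1)) < spec.medial_wall_radius
    valid = np.repeat(~cap[:, None], 2, axis=1)

    baseline = _harmonic_baseline(
        mesh.nodes, spec.baseline_mean, spec.baseline_amplitude, rng
    )

    effect_field = np.zeros(n)
    centers = []
    for center, radius, effect in spec.effect_regions:
        if radius <= 0:
            raise ValueError("effect region radius must be > 0")
        if radius > np.pi:
            raise ValueError("effect region radius exceeds the sphere")
        if center is None:
            d = _DEFAULT_CENTER_DIR / np.linalg.norm(_DEFAULT_CENTER_DIR)
            center = int(np.argmax(mesh.nodes @ d))
        taper = _region_taper(mesh, int(center), radius)
        if np.any(taper[cap] > 0):
            raise ValueError(
                f"effect region at node {center} overlaps the invalid cap"
            )
        effect_field = effect_field + effect * taper
        centers.append((int(center), radius, effect))

    y = np.repeat([0, 1], spec.n_per_class)
    X = np.broadcast_to(baseline[None, :, None], (s, n, 2)).copy()
    X[y == 1] += effect_field[:, None]
    X += _smooth_noise((s, n, 2), mesh, spec.smoothing_iters, spec.noise_sd, rng)
    X[:, ~valid[:, 0], :] = 0.0  # no measurement on the invalid cap

    truth = {
        "effect_field": np.repeat(effect_field[:, None], 2, axis=1),
        "region_mask": np.repeat((effect_field > 0)[:, None], 2, axis=1),
        "centers": centers,
        "baseline": baseline,
    }
    return Cohort(
        X=X, y=y, valid=valid, level=mesh.level, mesh=mesh, truth=truth, spec=spec
    )


def rotated_cohort(cohort: Cohort, rotation: SphericalRotation) -> Cohort:
    """The same cohort with every subject's maps globally rotated.

    Labels are unchanged; the truth record (effect field, region mask,
    centers) is transported by the same rotation, and both hemisphere
    channels are rotated identically.
    """
    idx = rotation_index(cohort.mesh, rotation)
    R = rotation.matrix()
    new_centers = []
    for c, radius, effect in cohort.truth["centers"]:
        moved = R @ cohort.mesh.nodes[c]
        new_centers.append(
            (int(np.argmax(cohort.mesh.nodes @ moved)), radius, effect)
        )
    truth = {
        "effect_field": cohort.truth["effect_field"][idx],
        "region_mask": cohort.truth["region_mask"][idx],
        "centers": new_centers,
        "baseline": cohort.truth["baseline"][idx],
    }
    return Cohort(
        X=cohort.X[:, idx, :],
        y=cohort.y.copy(),
        valid=cohort.valid[idx],
        level=cohort.level,
        mesh=cohort.mesh,
        truth=truth,
        spec=cohort.spec,
    )
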