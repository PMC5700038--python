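import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynifp as d

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


PDB_TWO_ATOMS = (
    "ATOM      1  N   LYS A 185      10.000  10.000  10.000  1.00  0.00           N\n"
    "ATOM      2  CA  LYS A 185      11.400  10.000  10.000  1.00  0.00           C\n"
    "END\n"
)


@pytest.fixture
def small_spec():
    """Six-residue chain + 5-atom ligand, no schedules."""
    return d.SyntheticSpec(n_residues=6, ligand_atoms=5, n_frames=10, seed=11)


@pytest.fixture
def small_topology(small_spec):
    return d.synth_topology(small_spec)


@pytest.fixture
def hbond_schedule():
    return d.ContactSchedule(
        d.ContactDefinition(kind="hbond", side_a=("A", 1, "SER"),
                            side_b=("A", 2, "TYR")),
        fraction=0.6, template="hbond-linear",
    )


def brute_force_vdw(coords, idx_a, idx_b, radii, elements):
    """O(N²) oracle for the any-pair vdW rule."""
    pairs = []
    for i in idx_a:
        for j in idx_b:
            r = radii.radius(elements[i]) + radii.radius(elements[j])
            if np.linalg.norm(coords[i] - coords[j]) <= r:
                pairs.append((i, j))
    return sorted(pairs)


def brute_force_hbond(coords, donors, acceptors, criteria):
    """O(N²) oracle for the distance+off-axis H-bond rule."""
    triples = []
    for g in donors:
        D, H = coords[g.donor_heavy], coords[g.hydrogen]
        for a in acceptors:
            if a in (g.donor_heavy, g.hydrogen):
                continue
            A = coords[a]
            dda = np.linalg.norm(D - A)
            if not (criteria.d_min <= dda <= criteria.d_max):
                continue
            v1, v2 = H - D, A - D
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang < criteria.max_off_axis_deg:
                triples.append((g.donor_heavy, g.hydrogen, a))
    return sorted(triples)


def rotation_grid_search_rmsd(mobile, reference, levels=5, n_per_axis=8):
    """Independent superposition oracle: zooming Euler-angle grid search.

    Centroids are aligned analytically; the rotation minimizing RMSD is
    found by successive grid refinement over (α, β, γ).
    """
    from scipy.spatial.transform import Rotation

    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rmsd_for(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    center = np.zeros(3)
    width = np.pi
    best = (np.inf, center)
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, n_per_axis) for c in best[1]]
        for a in axes[0]:
            for b in axes[1]:
                for g in axes[2]:
                    r = rmsd_for((a, b, g))
                    if r < best[0]:
                        best = (r, np.array([a, b, g]))
        width /= n_per_axis / 2.5
    return best[0]
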