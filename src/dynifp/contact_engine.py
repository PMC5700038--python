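"""Geometric contact detection: van der Waals contacts and hydrogen bonds.

A vdW contact between two atom selections is present in a frame when any
atom pair across the selections lies at or within the sum of the two
element vdW radii. A hydrogen bond D–H···A is present when the donor–
acceptor heavy-atom distance lies in [d_min, d_max] (inclusive, default
2.5–3.5 Å) and the off-axis angle — the deviation of the arrangement from
linearity, measured at the donor as angle(D→H, D→A) — is strictly below
the cutoff (default 30°). Donors and acceptors are restricted to N and O.

Both criteria are evaluated per frame over a trajectory to give a boolean
contact time series per residue pair (or residue–ligand pair).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Selection, Topology, Trajectory, select

__all__ = [
    "VdwRadiiTable",
    "HBondCriteria",
    "DonorGroup",
    "ContactDefinition",
    "ContactTimeSeries",
    "bondi_radii",
    "read_radii_tsv",
    "vdw_contact_present",
    "enumerate_donors_acceptors",
    "hbond_present",
    "residue_contact_series",
    "annotate_salt_bridge",
]

#: Positively charged side chains for salt-bridge annotation. Histidine is
#: included only via its protonated residue names.
_BASIC_RESNAMES = {"LYS", "ARG", "HIP", "HSP"}
_ACIDIC_RESNAMES = {"ASP", "GLU"}

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}

#: Max donor–hydrogen distance used to infer covalent D–H pairs from the
#: reference frame when no bond records exist.
DONOR_H_CUTOFF = 1.2  # Å


@dataclass(frozen=True)
class VdwRadiiTable:
    """Element → vdW radius (Å) with a provenance label."""

    radii: dict[str, float]
    provenance: str = "user"

    def __post_init__(self):
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {el} out of plausible range: {r}")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element.capitalize()]
        except KeyError:
            raise KeyError(f"no vdW radius for element {element!r}") from None

    def radii_for(self, elements: Sequence[str]) -> np.ndarray:
        return np.array([self.radius(e) for e in elements])


def read_radii_tsv(stream, provenance: str = "user") -> VdwRadiiTable:
    """Read a two-column TSV ``element<TAB>radius_A``; '#' lines ignored."""
    radii: dict[str, float] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, r = line.split("\t")[:2]
        radii[el.strip().capitalize()] = float(r)
    return VdwRadiiTable(radii=radii, provenance=provenance)


def bondi_radii() -> VdwRadiiTable:
    """The bundled Bondi (1964) element radii table."""
    ref = importlib.resources.files("dynifp") / "data" / "bondi_radii.tsv"
    with ref.open() as fh:
        return read_radii_tsv(fh, provenance="Bondi-1964")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Distance bounds are inclusive at both ends; the angle bound is strict.
    """

    d_min: float = 2.5
    d_max: float = 3.5
    max_off_axis_deg: float = 30.0
    #: "donor": off-axis angle measured at D as angle(D→H, D→A) — near-linear
    #: D–H···A gives small angles. "hydrogen": measured at H as the deviation
    #: of angle(H→D, H→A) from 180°.
    vertex: Literal["donor", "hydrogen"] = "donor"

    def __post_init__(self):
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")
        if not 0 < self.max_off_axis_deg < 90:
            raise ValueError("require 0 < max_off_axis_deg < 90")


@dataclass(frozen=True)
class DonorGroup:
    """A polar hydrogen and its covalently bound N/O heavy atom."""

    donor_heavy: int
    hydrogen: int


@dataclass(frozen=True)
class ContactDefinition:
    """One contact to monitor: kind + the two sides.

    Sides are residue keys ``(chain, residue_seq, residue_name)`` or the
    string ``"ligand"``. ``charged_pair_flag`` marks salt bridges (set by
    :func:`annotate_salt_bridge`).
    """

    kind: Literal["vdw", "hbond"]
    side_a: tuple[str, int, str] | str
    side_b: tuple[str, int, str] | str
    charged_pair_flag: bool = False

    def __post_init__(self):
        if self.kind not in ("vdw", "hbond"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.side_a == self.side_b:
            raise ValueError("contact sides must differ")

    def label(self, topology: Topology | None = None) -> str:
        def side(s):
            if s == "ligand":
                return "ligand"
            chain, seq, name = s
            bw = topology.bw_map.get(seq) if topology else None
            return f"{name}{seq}" + (f"^{bw}" if bw else "")
        return f"{side(self.side_a)}/{side(self.side_b)} [{self.kind}]"


@dataclass(frozen=True)
class ContactTimeSeries:
    """Boolean presence of one contact per frame of one replica."""

    definition: ContactDefinition
    replica_id: int
    condition: object
    presence: tuple[bool, ...]

    @property
    def n_frames(self) -> int:
        return len(self.presence)


# ---------------------------------------------------------------------------
# van der Waals contacts
# ---------------------------------------------------------------------------

def vdw_contact_present(coords: np.ndarray, sel_a: Selection, sel_b: Selection,
                        radii: VdwRadiiTable, elements: Sequence[str],
                        ) -> tuple[bool, list[tuple[int, int]]]:
    """Any-atom-pair vdW contact between two selections in one frame.

    Present iff some pair (i in a, j in b) satisfies ‖x_i − x_j‖ ≤ r_i + r_j
    (inclusive). Returns the presence flag and all qualifying (i, j) pairs in
    ascending (i, j) order. Uses a k-d tree pruned at the largest possible
    radius sum; results are identical to the brute-force O(N²) rule.
    """
    ia, ib = sel_a.as_array(), sel_b.as_array()
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("vdW contact requires two non-empty selections")
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections must be disjoint")
    xa, xb = coords[ia], coords[ib]
    ra = radii.radii_for([elements[i] for i in ia])
    rb = radii.radii_for([elements[j] for j in ib])
    rmax = ra.max() + rb.max()
    tree = cKDTree(xb)
    pairs: list[tuple[int, int]] = []
    for k, (x, r_i) in enumerate(zip(xa, ra)):
        for m in tree.query_ball_point(x, rmax):
            if np.linalg.norm(x - xb[m]) <= r_i + rb[m]:
                pairs.append((int(ia[k]), int(ib[m])))
    pairs.sort()
    return bool(pairs), pairs


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def enumerate_donors_acceptors(topology: Topology,
                               reference_coords: np.ndarray | None = None,
                               ) -> tuple[list[DonorGroup], list[int]]:
    """All N/O donors (with an attached H) and N/O acceptors of a topology.

    Hydrogens are assigned to the nearest N/O within ``DONOR_H_CUTOFF`` in
    the reference frame (topology coordinates by default); the assignment is
    re-used for all frames.
    """
    coords = topology.coords() if reference_coords is None else np.asarray(reference_coords)
    heavy = [i for i, a in enumerate(topology.atoms)
             if a.element in _DONOR_ACCEPTOR_ELEMENTS]
    hydrogens = [i for i, a in enumerate(topology.atoms) if a.element == "H"]
    donors: list[DonorGroup] = []
    if heavy and hydrogens:
        tree = cKDTree(coords[heavy])
        for h in hydrogens:
            dist, k = tree.query(coords[h], k=1)
            if dist <= DONOR_H_CUTOFF:
                donors.append(DonorGroup(donor_heavy=heavy[int(k)], hydrogen=h))
    donors.sort(key=lambda d: (d.donor_heavy, d.hydrogen))
    return donors, heavy


def _off_axis_deg(coords: np.ndarray, donor: DonorGroup, acceptor: int,
                  vertex: str) -> float:
    d = coords[donor.donor_heavy]
    h = coords[donor.hydrogen]
    a = coords[acceptor]
    if vertex == "donor":
        v1, v2 = h - d, a - d
        offset = 0.0
    else:  # hydrogen vertex: deviation of D–H–A from linear
        v1, v2 = d - h, a - h
        offset = 180.0
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return abs(ang - offset)


def hbond_present(coords: np.ndarray, donors: Iterable[DonorGroup],
                  acceptors: Iterable[int],
                  criteria: HBondCriteria = HBondCriteria(),
                  ) -> tuple[bool, list[tuple[int, int, int]]]:
    """Hydrogen-bond presence for one frame.

    Returns the flag and all qualifying (donor_heavy, hydrogen, acceptor)
    triples sorted ascending. An acceptor identical to the donor heavy atom
    or its hydrogen is skipped.
    """
    coords = np.asarray(coords)
    triples: list[tuple[int, int, int]] = []
    acceptors = list(acceptors)
    for g in donors:
        if not np.all(np.isfinite(coords[g.hydrogen])):
            raise ValueError(f"donor hydrogen {g.hydrogen} has no valid coordinates")
        for a in acceptors:
            if a == g.donor_heavy or a == g.hydrogen:
                continue
            # inclusive distance bounds, strict angle bound; 1e-9 guards keep
            # constructed boundary geometries on the documented side
            d_da = float(np.linalg.norm(coords[g.donor_heavy] - coords[a]))
            if not (criteria.d_min - 1e-9 <= d_da <= criteria.d_max + 1e-9):
                continue
            ang = _off_axis_deg(coords, g, a, criteria.vertex)
            if ang < criteria.max_off_axis_deg - 1e-9:
                triples.append((g.donor_heavy, g.hydrogen, a))
    triples.sort()
    return bool(triples), triples


# ---------------------------------------------------------------------------
# residue-level time series
# ---------------------------------------------------------------------------

def _side_selection(topology: Topology, side) -> Selection:
    if side == "ligand":
        return select(topology, "ligand")
    chain, seq, name = side
    return Selection(atom_indices=topology.atom_indices_of_residue(seq),
                     label=f"{name}{seq}")


def residue_contact_series(trajectory: Trajectory,
                           definition: ContactDefinition,
                           radii: VdwRadiiTable | None = None,
                           criteria: HBondCriteria = HBondCriteria(),
                           ) -> ContactTimeSeries:
    """Evaluate one contact definition over every frame of a trajectory.

    vdW contacts use the any-atom-pair radius-sum rule; hydrogen bonds are
    checked with donors/acceptors taken from both sides (donor on either
    side, acceptor on the other). The two kinds are independent: the same
    residue pair may carry both a vdw and an hbond definition.
    """
    top = trajectory.topology
    sel_a = _side_selection(top, definition.side_a)
    sel_b = _side_selection(top, definition.side_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError(f"empty selection for contact {definition.label()}")
    presence: list[bool] = []
    if definition.kind == "vdw":
        if radii is None:
            radii = bondi_radii()
        elements = top.elements()
        for frame in trajectory.coords:
            ok, _ = vdw_contact_present(frame, sel_a, sel_b, radii, elements)
            presence.append(ok)
    else:
        donors, acceptors = enumerate_donors_acceptors(top, trajectory.coords[0])
        a_set, b_set = set(sel_a.atom_indices), set(sel_b.atom_indices)

        def cross(donor_side: set[int], acceptor_side: set[int]):
            ds = [g for g in donors if g.donor_heavy in donor_side]
            as_ = [a for a in acceptors if a in acceptor_side]
            return ds, as_

        d_ab, a_ab = cross(a_set, b_set)
        d_ba, a_ba = cross(b_set, a_set)
        for frame in trajectory.coords:
            ok1, _ = hbond_present(frame, d_ab, a_ab, criteria) if d_ab and a_ab else (False, [])
            ok2, _ = hbond_present(frame, d_ba, a_ba, criteria) if d_ba and a_ba else (False, [])
            presence.append(ok1 or ok2)
    return ContactTimeSeries(definition=definition,
                             replica_id=trajectory.replica_id,
                             condition=trajectory.condition,
                             presence=tuple(presence))


def annotate_salt_bridge(definition: ContactDefinition,
                         topology: Topology) -> ContactDefinition:
    """Flag a residue pair as a salt bridge when the side chains carry
    opposite charges (Lys/Arg/His⁺ vs Asp/Glu). Detection geometry is
    unchanged: salt bridges are monitored with the hydrogen-bond criterion.
    """
    if definition.side_a == "ligand" or definition.side_b == "ligand":
        return definition
    name_a = definition.side_a[2].upper()
    name_b = definition.side_b[2].upper()
    charged = (
        (name_a in _BASIC_RESNAMES and name_b in _ACIDIC_RESNAMES)
        or (name_a in _ACIDIC_RESNAMES and name_b in _BASIC_RESNAMES)
    )
    return replace(definition, charged_pair_flag=charged)
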