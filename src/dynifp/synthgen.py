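"""Synthetic fixtures: topologies, trajectories with programmed contact
occupancies, diffusing-ligand point clouds and dose–response data.

The generator builds a minimal poly-residue chain in which every residue
carries a Cα, a carbon probe (CB) and, depending on the residue type, a
polar donor group and/or acceptor. Contact schedules move one residue (or
keep the ligand static and move its protein partner) between a geometry
that satisfies the contact criterion ("present" frames) and one that
violates it by at least the schedule margin ("absent" frames). Presence
frames are chosen by a seeded shuffle, so programmed occupancy fractions
are exact frame counts, and the whole output is a pure function of
(spec, seed). No physical realism is attempted: fixtures exercise the
geometry and the statistics, not force-field behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay import DosePoint, hill_response
from .contact_engine import ContactDefinition
from .structure_io import (
    AtomRecord,
    ConditionLabel,
    Topology,
    Trajectory,
)

__all__ = [
    "ContactSchedule",
    "SyntheticSpec",
    "synth_topology",
    "synth_trajectory",
    "synth_replica_set",
    "synth_ligand_cloud",
    "synth_dose_response",
]

#: Side-chain templates: (atom_name, element, local offset from the residue
#: anchor). Local x-offsets stay within 1 Å so scheduled separations along x
#: dominate every cross-residue atom distance.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "SER": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("OG", "O", (0.0, 3.0, 0.0)), ("HG", "H", (1.0, 3.0, 0.0))],
    "TYR": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("OH", "O", (0.0, 3.0, 0.0)), ("HH", "H", (1.0, 3.0, 0.0))],
    "LYS": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("NZ", "N", (0.0, 3.0, 0.0)), ("HZ1", "H", (1.0, 3.0, 0.0))],
    "ASN": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("OD1", "O", (0.0, 3.0, 0.0)), ("ND2", "N", (0.0, 4.5, 0.0)),
            ("HD21", "H", (1.0, 4.5, 0.0))],
    "ASP": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("OD1", "O", (0.0, 3.0, 0.0))],
    "HIS": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0)),
            ("ND1", "N", (0.0, 3.0, 0.0)), ("HD1", "H", (1.0, 3.0, 0.0))],
    "ALA": [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0))],
}
_DEFAULT_PALETTE = ("SER", "TYR", "LYS", "ASP", "ASN", "ALA")

#: Donor group (heavy, hydrogen) and acceptor atom names per residue type.
_DONOR_ATOMS = {"SER": ("OG", "HG"), "TYR": ("OH", "HH"), "LYS": ("NZ", "HZ1"),
                "ASN": ("ND2", "HD21"), "HIS": ("ND1", "HD1")}
_ACCEPTOR_ATOMS = {"SER": "OG", "TYR": "OH", "ASP": "OD1", "ASN": "OD1"}

_RESIDUE_PITCH = 20.0  # Å between residue anchors along x
# ligand anchor relative to chain end; off-lattice so base positions never
# sit exactly on 1 Å voxel boundaries
_LIGAND_OFFSET = np.array([0.3, 50.4, 0.7])
_MAX_RADIUS_SUM = 3.4  # Bondi C+C, the largest pair sum among C/N/O/H
_VDW_TOUCH_GAP = 0.2  # present vdW probe distance = r_sum − gap
_HBOND_PRESENT_DA = 3.0  # Å, mid-range donor–acceptor distance
_JITTER_SIGMA = 0.05  # Å, applied to atoms of unscheduled residues only


@dataclass(frozen=True)
class ContactSchedule:
    """Programmed occupancy of one contact.

    ``fraction`` is either one value for all replicas or one per replica.
    ``template`` selects the present-frame geometry; absent frames place the
    primary atom pair at least ``margin`` Å outside the criterion.
    """

    definition: ContactDefinition
    fraction: float | tuple[float, ...]
    template: str = "hbond-linear"
    margin: float = 1.0

    def __post_init__(self):
        if self.template not in ("vdw-touch", "hbond-linear"):
            raise ValueError(f"unknown geometry template {self.template!r}")
        if self.margin <= 0.1:
            raise ValueError("margin must exceed 0.1 Å")
        fr = self.fraction if isinstance(self.fraction, tuple) else (self.fraction,)
        if any(not 0 <= f <= 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")

    def fraction_for(self, replica_id: int) -> float:
        if isinstance(self.fraction, tuple):
            return self.fraction[replica_id - 1]
        return self.fraction


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything the generator needs, in one seeded record."""

    n_residues: int = 6
    ligand_atoms: int = 5
    n_frames: int = 100
    frame_dt_ns: float = 0.1
    schedules: tuple[ContactSchedule, ...] = ()
    seed: int = 0
    residue_names: tuple[str, ...] | None = None
    #: explicit residue numbers (e.g. receptor numbering); default 1..n
    residue_seqs: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.residue_seqs is not None:
            if len(set(self.residue_seqs)) != self.n_residues:
                raise ValueError("residue_seqs must be unique, one per residue")


def synth_topology(spec: SyntheticSpec) -> Topology:
    """Build the minimal chain + ligand topology for a spec.

    Residues sit ``_RESIDUE_PITCH`` Å apart along x; the HETATM ligand
    (``LIG``) sits 50 Å off the chain in y. BW codes are assigned
    sequentially (1.30, 1.31, …) unless residues are later re-mapped.
    """
    names = spec.residue_names or tuple(
        _DEFAULT_PALETTE[i % len(_DEFAULT_PALETTE)] for i in range(spec.n_residues)
    )
    if len(names) != spec.n_residues:
        raise ValueError("one residue name per residue required")
    atoms: list[AtomRecord] = []
    residues: list[tuple[str, int, str]] = []
    bw_map: dict[int, str] = {}
    serial = 1
    for i, resname in enumerate(names):
        if resname not in _RESIDUE_TEMPLATES:
            raise ValueError(f"no template for residue {resname!r}")
        seq = spec.residue_seqs[i] if spec.residue_seqs else i + 1
        # slight helical wobble keeps the Ca set non-collinear for fitting
        anchor = np.array([i * _RESIDUE_PITCH,
                           4.0 * np.sin(2.4 * i), 4.0 * np.cos(2.4 * i)])
        for name, element, offset in _RESIDUE_TEMPLATES[resname]:
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_seq=seq, chain="A",
                position=tuple(anchor + np.asarray(offset)),
            ))
            serial += 1
        residues.append(("A", seq, resname))
        bw_map[seq] = f"1.{30 + i}"
    if spec.ligand_atoms == 0:  # apo topology
        return Topology(atoms=tuple(atoms), residues=tuple(residues),
                        bw_map=bw_map)
    lig_anchor = np.array([spec.n_residues * _RESIDUE_PITCH, 0.0, 0.0]) + _LIGAND_OFFSET
    lig_seq = max(seq for _, seq, _ in residues) + 1
    for j in range(spec.ligand_atoms):
        atoms.append(AtomRecord(
            serial=serial, name=f"C{j + 1}", element="C", residue_name="LIG",
            residue_seq=lig_seq, chain="A",
            position=tuple(lig_anchor + np.array([0.0, 2.0 * j, 0.0])),
            is_hetatm=True,
        ))
        serial += 1
    residues.append(("A", lig_seq, "LIG"))
    return Topology(atoms=tuple(atoms), residues=tuple(residues), bw_map=bw_map,
                    ligand_resnames=frozenset({"LIG"}))


def _atom_index(topology: Topology, residue_seq: int, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.residue_seq == residue_seq and a.name == name:
            return i
    raise ValueError(f"atom {name} of residue {residue_seq} not found")


def _side_info(topology: Topology, side):
    """(residue_seq, residue_name, atom index tuple) for a schedule side."""
    if side == "ligand":
        idx = tuple(i for i, a in enumerate(topology.atoms) if a.is_hetatm)
        return topology.atoms[idx[0]].residue_seq, "LIG", idx
    chain, seq, name = side
    return seq, name, topology.atom_indices_of_residue(seq)


def _schedule_targets(topology: Topology, schedule: ContactSchedule):
    """Resolve anchor/mobile sides and present/absent mobile-side offsets.

    The mobile side is side_b unless side_b is the ligand (the ligand is
    always kept static). Returns (mobile atom indices, present displacement,
    absent displacement) where displacements translate the mobile side's
    base coordinates.
    """
    d = schedule.definition
    anchor_side, mobile_side = d.side_a, d.side_b
    if mobile_side == "ligand":
        anchor_side, mobile_side = mobile_side, anchor_side
    a_seq, a_name, a_idx = _side_info(topology, anchor_side)
    m_seq, m_name, m_idx = _side_info(topology, mobile_side)
    base = topology.coords()
    u = np.array([1.0, 0.0, 0.0])

    if schedule.template == "vdw-touch":
        anchor_probe = (a_idx[0] if anchor_side == "ligand"
                        else _atom_index(topology, a_seq, "CB"))
        mobile_probe = _atom_index(topology, m_seq, "CB")
        d_present = _MAX_RADIUS_SUM - _VDW_TOUCH_GAP
        # +1 Å guards the ≤1 Å local x-offsets of hydrogens on the mobile side
        d_absent = _MAX_RADIUS_SUM + schedule.margin + 1.0
    else:
        if anchor_side == "ligand":
            raise ValueError("hbond-linear schedules need a residue donor side")
        if a_name not in _DONOR_ATOMS:
            raise ValueError(f"residue {a_name} has no donor group")
        if m_name not in _ACCEPTOR_ATOMS:
            raise ValueError(f"residue {m_name} has no acceptor atom")
        anchor_probe = _atom_index(topology, a_seq, _DONOR_ATOMS[a_name][0])
        mobile_probe = _atom_index(topology, m_seq, _ACCEPTOR_ATOMS[m_name])
        d_present = _HBOND_PRESENT_DA
        d_absent = 3.5 + schedule.margin  # D–A just outside the inclusive bound

    present_pos = base[anchor_probe] + d_present * u
    absent_pos = base[anchor_probe] + d_absent * u
    return (np.asarray(m_idx, dtype=int),
            present_pos - base[mobile_probe],
            absent_pos - base[mobile_probe])


def synth_trajectory(topology: Topology, spec: SyntheticSpec, replica_id: int = 1,
                     condition: ConditionLabel | None = None) -> Trajectory:
    """Generate one replica with every schedule's occupancy exact.

    For each schedule, exactly ``round(fraction × n_frames)`` frames satisfy
    the contact criterion through the geometry template; the frame subset is
    a seeded shuffle derived from (spec.seed, replica_id, schedule index).
    Atoms of unscheduled residues get σ = 0.05 Å Gaussian jitter.
    """
    base = topology.coords()
    n = spec.n_frames
    coords = np.repeat(base[None, :, :], n, axis=0)

    mobile_seen: set = set()
    pairs_seen: set = set()
    scheduled_atoms: set[int] = set()
    rng_root = np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(replica_id,)))

    for j, sched in enumerate(spec.schedules):
        d = sched.definition
        pair_key = frozenset((repr(d.side_a), repr(d.side_b)))
        if pair_key in pairs_seen:
            raise ValueError(f"conflicting schedules on pair {d.label()}")
        pairs_seen.add(pair_key)
        m_idx, dp, da = _schedule_targets(topology, sched)
        if m_idx[0] in mobile_seen:
            raise ValueError(
                f"residue moved by two schedules: {d.label()}")
        mobile_seen.update(m_idx)
        scheduled_atoms.update(m_idx)
        for side in (d.side_a, d.side_b):
            scheduled_atoms.update(_side_info(topology, side)[2])

        frac = sched.fraction_for(replica_id)
        n_present = round(frac * n)
        if abs(frac * n - n_present) > 1e-9:
            raise ValueError(
                f"fraction {frac} × {n} frames is not integral for {d.label()}")
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(replica_id, j)))
        order = rng.permutation(n)
        present = np.zeros(n, dtype=bool)
        present[order[:n_present]] = True
        for f in range(n):
            coords[f, m_idx] = base[m_idx] + (dp if present[f] else da)

    free = np.array([i for i in range(topology.n_atoms) if i not in scheduled_atoms])
    if len(free):
        # margin ≥ 0.5 Å keeps 0.05 Å jitter from ever crossing a boundary
        assert all(s.margin >= 0.5 for s in spec.schedules) or not spec.schedules
        coords[:, free, :] += rng_root.normal(0.0, _JITTER_SIGMA,
                                              size=(n, len(free), 3))
    times = tuple(i * spec.frame_dt_ns for i in range(n))
    return Trajectory(topology=topology, times_ns=times, coords=coords,
                      replica_id=replica_id, condition=condition)


def synth_replica_set(topology: Topology, spec: SyntheticSpec,
                      fractions: Sequence[float | Sequence[float]] | None = None,
                      condition: ConditionLabel | None = None) -> list[Trajectory]:
    """Generate replicas 1..n with per-replica fractions.

    ``fractions`` has one entry per replica: a scalar applied to every
    schedule or a sequence with one value per schedule. When omitted, the
    schedules' own per-replica fractions are used and the replica count is
    taken from the first schedule.
    """
    if fractions is None:
        first = spec.schedules[0].fraction
        n_rep = len(first) if isinstance(first, tuple) else 1
        reps = range(1, n_rep + 1)
        specs = [spec] * n_rep
    else:
        reps = range(1, len(fractions) + 1)
        specs = []
        for fr in fractions:
            if np.isscalar(fr):
                scheds = tuple(
                    ContactSchedule(s.definition, float(fr), s.template, s.margin)
                    for s in spec.schedules)
            else:
                scheds = tuple(
                    ContactSchedule(s.definition, float(f), s.template, s.margin)
                    for s, f in zip(spec.schedules, fr))
            specs.append(SyntheticSpec(
                n_residues=spec.n_residues, ligand_atoms=spec.ligand_atoms,
                n_frames=spec.n_frames, frame_dt_ns=spec.frame_dt_ns,
                schedules=scheds, seed=spec.seed,
                residue_names=spec.residue_names,
                residue_seqs=spec.residue_seqs))
    return [synth_trajectory(topology, s, replica_id=r, condition=condition)
            for r, s in zip(reps, specs)]


def synth_ligand_cloud(origin: Sequence[float], extent: Sequence[float],
                       n_frames: int, n_atoms: int, seed: int,
                       frame_dt_ns: float = 0.1) -> Trajectory:
    """Uniform i.i.d. ligand positions inside a box, as a trajectory over a
    minimal ligand-only topology."""
    origin = np.asarray(origin, dtype=float)
    extent = np.asarray(extent, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("box extent must be positive")
    atoms = tuple(
        AtomRecord(serial=j + 1, name=f"C{j + 1}", element="C",
                   residue_name="LIG", residue_seq=1, chain="A",
                   position=tuple(origin), is_hetatm=True)
        for j in range(n_atoms)
    )
    top = Topology(atoms=atoms, residues=(("A", 1, "LIG"),),
                   ligand_resnames=frozenset({"LIG"}))
    rng = np.random.default_rng(seed)
    coords = origin + rng.random((n_frames, n_atoms, 3)) * extent
    times = tuple(i * frame_dt_ns for i in range(n_frames))
    return Trajectory(topology=top, times_ns=times, coords=coords)


def synth_dose_response(baseline: float, amplitude: float, ec50: float,
                        hill_n: float, concentrations: Sequence[float],
                        noise_sd: float = 0.0, seed: int = 0) -> list[DosePoint]:
    """Hill-curve responses with seeded Gaussian noise."""
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    points = []
    for c in concentrations:
        y = hill_response(c, baseline, amplitude, ec50, hill_n)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        points.append(DosePoint(concentration=float(c), normalized_response=float(y)))
    return points
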