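"""Topology and trajectory I/O for fingerprint analysis.

Reads fixed-column PDB topologies and multi-model PDB trajectories,
attaches Ballesteros–Weinstein (BW) numbering and per-condition metadata,
slices assessment windows, and resolves atom selections.

Units are Å for coordinates and ns for times throughout.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "ConditionLabel",
    "Selection",
    "PDBParseError",
    "read_pdb_topology",
    "read_multimodel_trajectory",
    "write_pdb",
    "write_multimodel_pdb",
    "write_frames",
    "read_frames",
    "attach_bw_map",
    "read_bw_map_tsv",
    "slice_assessment_window",
    "select",
    "SelectionSyntaxError",
]

LIGANDS = ("R-alpha-ionone", "S-alpha-ionone", "beta-ionone", "apo")
STATES = ("inactive", "active")

#: Roman-numeral helix names accepted by `helix` selections, in TM order.
HELIX_NAMES = ("I", "II", "III", "IV", "V", "VI", "VII")

# Residue names treated as solvent, never as ligand, when guessing
# ligand residues from HETATM records.
_SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC", "NA", "CL", "K", "MG"}

# Two-letter elements recognised by the atom-name fallback.  CA/NA/HG are
# deliberately absent: in protein context those names are far more likely
# to be an alpha carbon, a sodium-named nitrogen variant or a mercury-free
# hydrogen than the metals.
_TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "SE", "SI"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: tuple[float, float, float]
    is_hetatm: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


@dataclass(frozen=True)
class ConditionLabel:
    """Ligand × receptor-state condition of a simulation."""

    ligand: str
    state: str

    def __post_init__(self):
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}; expected one of {LIGANDS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    def __str__(self) -> str:
        return f"{self.ligand}/{self.state}"


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom-index set resolved against a topology."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("duplicate atom indices in selection")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


@dataclass(frozen=True)
class Topology:
    """Atoms plus residue table, BW numbering and helix annotation.

    ``residues`` holds unique ``(chain, residue_seq, residue_name)`` keys in
    file order. ``bw_map`` maps residue_seq → BW code (e.g. ``"6.48"``);
    ``helix_ranges`` maps helix name (``"I"``…``"VII"``) → inclusive
    ``(first_seq, last_seq)`` interval.
    """

    atoms: tuple[AtomRecord, ...]
    residues: tuple[tuple[str, int, str], ...]
    bw_map: Mapping[int, str] = field(default_factory=dict)
    helix_ranges: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    ligand_resnames: frozenset[str] = frozenset()

    def __post_init__(self):
        seqs = {seq for _, seq, _ in self.residues}
        for key in self.bw_map:
            if key not in seqs:
                raise ValueError(f"bw_map key {key} is not a residue of this topology")
        ranges = sorted(self.helix_ranges.values())
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if b0 <= a1:
                raise ValueError("helix_ranges must be disjoint")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_by_bw(self, code: str) -> tuple[str, int, str]:
        """Resolve a BW code like ``"6.48"`` to its residue key."""
        for seq, bw in self.bw_map.items():
            if bw == code:
                for key in self.residues:
                    if key[1] == seq:
                        return key
        raise KeyError(f"no residue mapped to BW code {code!r}")

    def atom_indices_of_residue(self, residue_seq: int) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if a.residue_seq == residue_seq)


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames over a fixed topology, with replica/condition metadata."""

    topology: Topology
    times_ns: tuple[float, ...]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    replica_id: int = 1
    condition: ConditionLabel | None = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.ndim != 3 or c.shape[1] != self.topology.n_atoms or c.shape[2] != 3:
            raise ValueError(
                f"coords shape {c.shape} does not match topology with "
                f"{self.topology.n_atoms} atoms"
            )
        if len(self.times_ns) != c.shape[0]:
            raise ValueError("one time per frame required")
        t = np.asarray(self.times_ns)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_ns(self) -> float:
        if self.n_frames == 0:
            return 0.0
        return self.times_ns[-1] - self.times_ns[0]


# ---------------------------------------------------------------------------
# PDB fixed-column parsing
# ---------------------------------------------------------------------------

def _infer_element(raw_element: str, atom_name: str) -> str:
    """Element from columns 77–78, else first alphabetic char of the name
    (with a two-letter exception list for halogens/metals)."""
    e = raw_element.strip()
    if e:
        return e.capitalize()
    name = atom_name.strip()
    head = re.sub(r"[^A-Za-z].*", "", name).upper()
    if head[:2] in _TWO_LETTER_ELEMENTS:
        return head[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
    element = _infer_element(line[76:78] if len(line) >= 78 else "", name)
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain=chain,
        position=(x, y, z),
        is_hetatm=line.startswith("HETATM"),
    )


def read_pdb_topology(stream) -> Topology:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Topology`.

    Parameters
    ----------
    stream
        Text stream or string containing PDB fixed-column records. Only the
        first model of a multi-model file contributes atoms.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    atoms: list[AtomRecord] = []
    residues: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    in_first_model = True
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            in_first_model = False
        if not in_first_model:
            continue
        if rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line.rstrip("\n"), lineno)
            atoms.append(atom)
            key = (atom.chain, atom.residue_seq, atom.residue_name)
            if key not in seen:
                seen.add(key)
                residues.append(key)
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    ligand_resnames = frozenset(
        a.residue_name
        for a in atoms
        if a.is_hetatm and a.residue_name not in _SOLVENT_RESNAMES
    )
    return Topology(
        atoms=tuple(atoms),
        residues=tuple(residues),
        ligand_resnames=ligand_resnames,
    )


def read_multimodel_trajectory(stream, topology: Topology, time_step_ns: float,
                               replica_id: int = 1,
                               condition: ConditionLabel | None = None) -> Trajectory:
    """Read MODEL/ENDMDL blocks as trajectory frames.

    Frame *i* (0-based model order) gets time ``i * time_step_ns``. Every
    model must contain exactly the topology's atom count.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] | None = None
    model_no = 0
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            model_no += 1
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
            if len(current) != topology.n_atoms:
                raise PDBParseError(
                    f"model {model_no}: expected {topology.n_atoms} atoms, "
                    f"got {len(current)}"
                )
            frames.append(np.asarray(current, dtype=float))
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line.rstrip("\n"), lineno)
            if current is None:
                # single implicit model
                model_no = max(model_no, 1)
                current = []
            current.append(atom.position)
    if current:
        if len(current) != topology.n_atoms:
            raise PDBParseError(
                f"model {model_no}: expected {topology.n_atoms} atoms, got {len(current)}"
            )
        frames.append(np.asarray(current, dtype=float))
    if not frames:
        raise PDBParseError("no coordinate models found")
    times = tuple(i * time_step_ns for i in range(len(frames)))
    return Trajectory(topology=topology, times_ns=times,
                      coords=np.stack(frames), replica_id=replica_id,
                      condition=condition)


def _format_atom_line(atom: AtomRecord, position) -> str:
    rec = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = position
    return (
        f"{rec}{atom.serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{atom.chain:1.1s}{atom.residue_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2.2s}"
    )


def write_pdb(topology: Topology, stream, coords: np.ndarray | None = None) -> None:
    """Write a single-model PDB (topology coordinates unless given)."""
    frame = topology.coords() if coords is None else np.asarray(coords)
    for atom, pos in zip(topology.atoms, frame):
        stream.write(_format_atom_line(atom, pos) + "\n")
    stream.write("END\n")


def write_multimodel_pdb(trajectory: Trajectory, stream) -> None:
    """Write frames as MODEL/ENDMDL blocks (coordinates at PDB 1e-3 Å
    precision)."""
    for i, frame in enumerate(trajectory.coords, start=1):
        stream.write(f"MODEL     {i:>4d}\n")
        for atom, pos in zip(trajectory.topology.atoms, frame):
            stream.write(_format_atom_line(atom, pos) + "\n")
        stream.write("ENDMDL\n")
    stream.write("END\n")


# ---------------------------------------------------------------------------
# Internal frame format: plain-text, whitespace-separated
# ---------------------------------------------------------------------------

_FRAMES_MAGIC = "DYNIFP-FRAMES 1"


def write_frames(trajectory: Trajectory, stream) -> None:
    """Write frames in the internal plain-text format.

    Header line ``DYNIFP-FRAMES 1 <n_frames> <n_atoms>``, then one block per
    frame: a line ``t <time_ns>`` followed by one ``x y z`` line per atom
    (full float repr, so round-trips are exact well below PDB precision).
    """
    stream.write(f"{_FRAMES_MAGIC} {trajectory.n_frames} {trajectory.topology.n_atoms}\n")
    for t, frame in zip(trajectory.times_ns, trajectory.coords):
        stream.write(f"t {float(t)!r}\n")
        for x, y, z in frame:
            stream.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_frames(stream, topology: Topology, replica_id: int = 1,
                condition: ConditionLabel | None = None) -> Trajectory:
    """Read the internal frame format back into a :class:`Trajectory`."""
    header = stream.readline().split()
    if header[:2] != _FRAMES_MAGIC.split():
        raise PDBParseError("not a DYNIFP-FRAMES stream")
    n_frames, n_atoms = int(header[2]), int(header[3])
    if n_atoms != topology.n_atoms:
        raise PDBParseError(
            f"frame file has {n_atoms} atoms but topology has {topology.n_atoms}"
        )
    times = []
    coords = np.empty((n_frames, n_atoms, 3), dtype=float)
    for f in range(n_frames):
        tline = stream.readline().split()
        if not tline or tline[0] != "t":
            raise PDBParseError(f"frame {f + 1}: missing time line")
        times.append(float(tline[1]))
        for a in range(n_atoms):
            coords[f, a] = [float(v) for v in stream.readline().split()]
    return Trajectory(topology=topology, times_ns=tuple(times), coords=coords,
                      replica_id=replica_id, condition=condition)


# ---------------------------------------------------------------------------
# BW numbering
# ---------------------------------------------------------------------------

def read_bw_map_tsv(stream) -> dict[int, str]:
    """Read a two-column TSV ``residue_seq<TAB>bw_code``; '#' lines ignored."""
    mapping: dict[int, str] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seq, code = line.split("\t")[:2]
        mapping[int(seq)] = code.strip()
    return mapping


def attach_bw_map(topology: Topology, mapping: Mapping[int, str]) -> Topology:
    """Return a topology with the BW map attached.

    Raises ``ValueError`` listing every mapping key that is not a residue of
    the topology.
    """
    seqs = {seq for _, seq, _ in topology.residues}
    unknown = sorted(k for k in mapping if k not in seqs)
    if unknown:
        raise ValueError(f"bw_map keys not in topology: {unknown}")
    return replace(topology, bw_map=dict(mapping))


# ---------------------------------------------------------------------------
# Assessment window
# ---------------------------------------------------------------------------

def slice_assessment_window(trajectory: Trajectory, window_ns: float) -> Trajectory:
    """Keep frames in the half-open interval (t_end − window, t_end].

    A window equal to the full duration returns the trajectory unchanged
    (degenerate closed case). A window longer than the duration is an error,
    with one frame-step of slack so the operation is idempotent: a sliced
    trajectory covers (t_end − w, t_end] but its first retained frame sits up
    to one step inside it.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    duration = trajectory.duration_ns
    eps = 1e-9
    steps = np.diff(trajectory.times_ns)
    step = float(np.median(steps)) if len(steps) else 0.0
    if window_ns > duration + step + eps:
        raise ValueError(
            f"window {window_ns} ns exceeds trajectory duration {duration} ns"
        )
    if window_ns >= duration - eps:
        return trajectory
    t_end = trajectory.times_ns[-1]
    cut = t_end - window_ns
    keep = [i for i, t in enumerate(trajectory.times_ns) if t > cut + eps]
    return Trajectory(
        topology=trajectory.topology,
        times_ns=tuple(trajectory.times_ns[i] for i in keep),
        coords=trajectory.coords[keep],
        replica_id=trajectory.replica_id,
        condition=trajectory.condition,
    )


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

class SelectionSyntaxError(ValueError):
    """Selection-expression syntax error, carrying the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.'\-]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if not m:
            raise SelectionSyntaxError("unexpected character", pos)
        if m.group(1):
            tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    """Recursive-descent parser for the small selection grammar.

    expr    := term ('or' term)*
    term    := factor ('and' factor)*
    factor  := 'not' factor | '(' expr ')' | primitive
    primitive := 'resid' range+ | 'resname' NAME+ | 'name' NAME+
               | 'element' NAME+ | 'helix' helixrange+ | 'ligand' | 'all'
    """

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology):
        self.tokens = tokens
        self.i = 0
        self.top = topology
        self.n = topology.n_atoms

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self):
        return self.tokens[self.i][1] if self.i < len(self.tokens) else -1

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.i < len(self.tokens):
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}", self.pos())
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.advance()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.advance()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.advance()
            return ~self.factor()
        if tok == "(":
            self.advance()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionSyntaxError("expected ')'", self.pos())
            self.advance()
            return mask
        return self.primitive()

    _KEYWORDS = {"and", "or", "not", ")", "("}

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in self._KEYWORDS:
            vals.append(self.advance()[0])
        if not vals:
            raise SelectionSyntaxError("expected at least one value", self.pos())
        return vals

    def primitive(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", len(self.tokens))
        if tok == "ligand":
            self.advance()
            return np.array(
                [a.is_hetatm and a.residue_name in self.top.ligand_resnames
                 for a in self.top.atoms]
            )
        if tok == "all":
            self.advance()
            return np.ones(self.n, dtype=bool)
        if tok == "resid":
            self.advance()
            wanted: set[int] = set()
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", v)
                try:
                    if m:
                        wanted.update(range(int(m.group(1)), int(m.group(2)) + 1))
                    else:
                        wanted.add(int(v))
                except ValueError:
                    raise SelectionSyntaxError(f"bad resid value {v!r}", self.pos())
            return np.array([a.residue_seq in wanted for a in self.top.atoms])
        if tok == "resname":
            self.advance()
            names = {v.upper() for v in self._values()}
            return np.array([a.residue_name.upper() in names for a in self.top.atoms])
        if tok == "name":
            self.advance()
            names = {v.upper() for v in self._values()}
            return np.array([a.name.upper() in names for a in self.top.atoms])
        if tok == "element":
            self.advance()
            els = {v.capitalize() for v in self._values()}
            return np.array([a.element in els for a in self.top.atoms])
        if tok == "helix":
            self.advance()
            names: set[str] = set()
            for v in self._values():
                v = v.upper()
                if "-" in v:
                    lo, hi = v.split("-", 1)
                    if lo not in HELIX_NAMES or hi not in HELIX_NAMES:
                        raise SelectionSyntaxError(f"unknown helix range {v!r}", self.pos())
                    i0, i1 = HELIX_NAMES.index(lo), HELIX_NAMES.index(hi)
                    names.update(HELIX_NAMES[i0:i1 + 1])
                else:
                    if v not in HELIX_NAMES:
                        raise SelectionSyntaxError(f"unknown helix {v!r}", self.pos())
                    names.add(v)
            mask = np.zeros(self.n, dtype=bool)
            for h in names:
                if h in self.top.helix_ranges:
                    lo, hi = self.top.helix_ranges[h]
                    mask |= np.array(
                        [lo <= a.residue_seq <= hi for a in self.top.atoms]
                    )
            return mask
        raise SelectionSyntaxError(f"unknown selection keyword {tok!r}", self.pos())


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to an ordered atom-index set.

    Grammar: ``resid`` (single ids or ``lo-hi`` ranges), ``resname``,
    ``name``, ``element``, ``helix I``/``helix I-VII``, ``ligand``, ``all``,
    combined with ``and``/``or``/``not`` and parentheses. Matching nothing
    yields an empty selection, not an error.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty expression", 0)
    mask = _SelParser(tokens, topology).parse()
    return Selection(atom_indices=tuple(int(i) for i in np.flatnonzero(mask)),
                     label=expression)
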