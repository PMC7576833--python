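"""Antibody structures, trajectories and region annotation.

This module provides the containers every downstream stage consumes: a
:class:`Topology` (atoms, residues, masses), a :class:`Trajectory`
(frames x atoms x 3 coordinates in Angstrom) and :class:`AntibodyRegions`
(named residue sets for the variable/constant domains, the six CDR loops,
the optional DE loops and the switch regions linking the variable and
constant modules of a Fab).

PDB input/output is delegated to :mod:`biotite`; this module adds the
validation and error semantics the pipeline relies on (altloc resolution,
duplicate-atom detection, model-consistency checks) and the residue-set
arithmetic for antibody regions.  Residue identity is insertion-code aware
throughout, as antibody numbering requires.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Residue",
    "Topology",
    "Trajectory",
    "AntibodyRegions",
    "PDBParseError",
    "RegionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "annotate_regions",
    "CHOTHIA_CDRS",
    "NORTH_CDRS",
]


class PDBParseError(ValueError):
    """Raised when a PDB-dialect text cannot be interpreted."""


class RegionError(ValueError):
    """Raised when a region definition does not match the topology."""


DOMAIN_NAMES = ("VL", "VH", "CL", "CH1")
LIGHT_CDRS = ("CDR-L1", "CDR-L2", "CDR-L3")
HEAVY_CDRS = ("CDR-H1", "CDR-H2", "CDR-H3")
DE_LOOPS = ("CDR-L4", "CDR-H4")
CDR_TO_DOMAIN = {
    **{c: "VL" for c in LIGHT_CDRS + ("CDR-L4",)},
    **{c: "VH" for c in HEAVY_CDRS + ("CDR-H4",)},
}

#: Chothia CDR boundaries (Chothia numbering), provided as an explicit
#: preset only; they are never applied implicitly because deposited
#: structures use heterogeneous numbering conventions.
CHOTHIA_CDRS = {
    "CDR-L1": (24, 34),
    "CDR-L2": (50, 56),
    "CDR-L3": (89, 97),
    "CDR-H1": (26, 32),
    "CDR-H2": (52, 56),
    "CDR-H3": (95, 102),
}

#: North et al. CDR boundaries (North/AHo-style clustering convention).
NORTH_CDRS = {
    "CDR-L1": (24, 34),
    "CDR-L2": (49, 56),
    "CDR-L3": (89, 97),
    "CDR-H1": (23, 35),
    "CDR-H2": (50, 58),
    "CDR-H3": (93, 102),
}


@dataclass(frozen=True)
class Residue:
    """Insertion-code-aware residue identity."""

    chain_id: str
    res_id: int
    ins_code: str = ""
    res_name: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.ins_code)

    def __str__(self) -> str:  # e.g. "L:27A (SER)"
        code = f"{self.res_id}{self.ins_code}"
        return f"{self.chain_id}:{code}"


@dataclass
class Topology:
    """Atoms and residues of one molecular system.

    ``res_index[i]`` maps atom ``i`` into ``residues``.  Masses are in amu.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    res_index: np.ndarray
    residues: list[Residue]

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.res_index = np.asarray(self.res_index, dtype=int)
        if self.n_atoms == 0:
            raise ValueError("topology must contain at least one atom")
        if self.res_index.max() >= len(self.residues) or self.res_index.min() < 0:
            raise ValueError("atom residue index outside residue table")
        if not np.all(self.masses > 0):
            raise ValueError("all atomic masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_key_map(self) -> dict[tuple[str, int, str], int]:
        return {r.key: i for i, r in enumerate(self.residues)}

    def atoms_of_residues(
        self, residue_indices: Iterable[int], atom_filter: Sequence[str] | None = None
    ) -> np.ndarray:
        """Atom indices belonging to the given residues (optionally by name)."""
        wanted = np.isin(self.res_index, np.fromiter(residue_indices, dtype=int))
        if atom_filter is not None:
            wanted &= np.isin(self.atom_names, np.asarray(atom_filter, dtype=object))
        return np.nonzero(wanted)[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            list(self.atom_names) == list(other.atom_names)
            and list(self.elements) == list(other.elements)
            and np.allclose(self.masses, other.masses)
            and np.array_equal(self.res_index, other.res_index)
            and self.residues == other.residues
        )


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology (Angstrom)."""

    topology: Topology
    coords: np.ndarray
    frame_spacing: float | None = None  # time per saved frame, ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class AntibodyRegions:
    """Named residue-index sets over one topology.

    Keys follow the field's conventions: ``VL``/``VH`` (variable domains),
    ``CL``/``CH1`` (first constant domains), ``CDR-L1``..``CDR-H3`` (the six
    hypervariable loops), optional DE loops ``CDR-L4``/``CDR-H4`` and
    ``switch_L``/``switch_H`` (the residues linking the variable and constant
    modules on each chain).
    """

    sets: dict[str, frozenset[int]]
    scheme: str = "explicit"

    def __getitem__(self, name: str) -> frozenset[int]:
        try:
            return self.sets[name]
        except KeyError:
            raise RegionError(f"region {name!r} is not defined") from None

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def get(self, name: str) -> frozenset[int] | None:
        return self.sets.get(name)

    def union(self, names: Iterable[str]) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for n in names:
            out |= self[n]
        return out

    @property
    def light_cdrs(self) -> frozenset[int]:
        return self.union(n for n in LIGHT_CDRS if n in self.sets)

    @property
    def heavy_cdrs(self) -> frozenset[int]:
        return self.union(n for n in HEAVY_CDRS if n in self.sets)

    @property
    def all_cdrs(self) -> frozenset[int]:
        return self.light_cdrs | self.heavy_cdrs

    def framework(self) -> frozenset[int]:
        """Fv residues outside every CDR loop (DE loops stay in framework)."""
        fv = self["VL"] | self["VH"]
        return fv - self.all_cdrs


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, element: str) -> str:
    if element:
        return element.strip().capitalize()
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def _check_duplicates(text: str) -> None:
    """Reject files holding the same atom twice within a residue+altloc."""
    seen: set[tuple] = set()
    model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            model += 1
            seen = set()
        elif rec in ("ATOM  ", "HETATM"):
            key = (
                model,
                line[21],           # chain
                line[22:27].strip(),  # resid + insertion code
                line[12:16].strip(),  # atom name
                line[16],           # altloc
            )
            if key in seen:
                raise PDBParseError(
                    f"duplicate atom record at line {lineno}: {line.rstrip()!r}"
                )
            seen.add(key)


def _topology_from_atom_array(arr) -> Topology:
    residues: list[Residue] = []
    key_to_idx: dict[tuple[str, int, str], int] = {}
    res_index = np.empty(arr.array_length(), dtype=int)
    elements = []
    masses = np.empty(arr.array_length(), dtype=float)
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]))
        if key not in key_to_idx:
            key_to_idx[key] = len(residues)
            residues.append(Residue(*key, res_name=str(arr.res_name[i])))
        res_index[i] = key_to_idx[key]
        elem = _infer_element(str(arr.atom_name[i]), str(arr.element[i]))
        elements.append(elem)
        m = struc_info.mass(elem)
        masses[i] = m if m else 12.011
    return Topology(
        atom_names=np.asarray(arr.atom_name, dtype=object),
        elements=np.asarray(elements, dtype=object),
        masses=masses,
        res_index=res_index,
        residues=residues,
    )


def read_structure(pdb_text: str, frame_spacing: float | None = None) -> Trajectory:
    """Parse PDB-dialect text into a trajectory (one frame per MODEL).

    Alternate locations are resolved to the highest occupancy; ties go to
    the first-listed (alphabetically smallest) altloc identifier.
    """
    if not any(
        line.startswith(("ATOM  ", "HETATM")) for line in pdb_text.splitlines()
    ):
        raise PDBParseError("no ATOM records found")
    _check_duplicates(pdb_text)
    pdb = PDBFile.read(io.StringIO(pdb_text))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # inconsistent MODELs etc.
        raise PDBParseError(str(exc)) from exc
    topology = _topology_from_atom_array(stack[0] if stack.stack_depth() else stack)
    return Trajectory(topology=topology, coords=np.asarray(stack.coord, dtype=float),
                      frame_spacing=frame_spacing)


def read_trajectory(
    files: Sequence[str | io.TextIOBase],
    topology: Topology,
    frame_spacing: float | None = None,
) -> Trajectory:
    """Concatenate multi-model PDB files, in file order, over one topology."""
    if len(files) == 0:
        raise ValueError("empty file list")
    chunks = []
    for f in files:
        if hasattr(f, "read"):
            text, name = f.read(), getattr(f, "name", "<stream>")
        else:
            with open(f) as handle:
                text = handle.read()
            name = str(f)
        traj = read_structure(text)
        if traj.n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom-count mismatch in {name}: file has {traj.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        chunks.append(traj.coords)
    return Trajectory(topology=topology, coords=np.concatenate(chunks, axis=0),
                      frame_spacing=frame_spacing)


def write_structure(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text (inverse of reading)."""
    top = traj.topology
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([top.residues[j].chain_id for j in top.res_index])
    arr.res_id = np.array([top.residues[j].res_id for j in top.res_index])
    arr.ins_code = np.array([top.residues[j].ins_code for j in top.res_index])
    arr.res_name = np.array([top.residues[j].res_name or "UNK" for j in top.res_index])
    arr.atom_name = np.asarray(top.atom_names, dtype="U6")
    arr.element = np.asarray(top.elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.from_template(arr, traj.coords)
    out = PDBFile()
    out.set_structure(stack)
    sio = io.StringIO()
    out.write(sio)
    return sio.getvalue()


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

def _resolve_ranges(
    topology: Topology,
    name: str,
    ranges: Sequence[tuple[str, int, int]],
) -> frozenset[int]:
    key_map: dict[str, dict[tuple[int, str], int]] = {}
    for idx, res in enumerate(topology.residues):
        key_map.setdefault(res.chain_id, {})[(res.res_id, res.ins_code)] = idx
    out: set[int] = set()
    for chain, start, stop in ranges:
        chain_map = key_map.get(str(chain))
        if chain_map is None:
            raise RegionError(f"region {name!r}: chain {chain!r} not in topology")
        hit = False
        for (rid, _icode), idx in chain_map.items():
            if start <= rid <= stop:
                out.add(idx)
                hit = True
        if not hit:
            raise RegionError(
                f"region {name!r}: no residues {chain}:{start}-{stop} in topology"
            )
    if not out:
        raise RegionError(f"region {name!r} has no residues")
    return frozenset(out)


def _normalise_config(region_config: Mapping) -> dict[str, list[tuple[str, int, int]]]:
    """Accept {name: (chain, start, stop)} or {name: [(chain, start, stop), ...]}
    or the flat text form {name: "L:24-34"}."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for name, value in region_config.items():
        if isinstance(value, str):
            chain, span = value.split(":")
            lo, _, hi = span.partition("-")
            ranges = [(chain, int(lo), int(hi or lo))]
        elif isinstance(value, tuple) and len(value) == 3:
            ranges = [value]
        else:
            ranges = [tuple(v) for v in value]
        out[str(name)] = [(str(c), int(a), int(b)) for c, a, b in ranges]
    return out


def _default_switch(
    topology: Topology, variable: frozenset[int], constant: frozenset[int]
) -> frozenset[int]:
    """Default switch region: the 4 residues flanking the V/C junction
    (last 2 of the variable domain, first 2 of the constant domain)."""
    def ordered(idx_set):
        return sorted(idx_set, key=lambda i: (topology.residues[i].res_id,
                                              topology.residues[i].ins_code))
    v_sorted = ordered(variable)
    c_sorted = ordered(constant)
    return frozenset(v_sorted[-2:] + c_sorted[:2])


def annotate_regions(topology: Topology, region_config: Mapping) -> AntibodyRegions:
    """Resolve a region configuration into validated residue-index sets.

    The configuration maps region names (``VL``, ``CDR-H3``, ...) to
    chain/residue-range specifications.  Validation enforces the structural
    invariants: every CDR set lies inside its domain, domains are pairwise
    disjoint, CDR loops are pairwise disjoint, and every referenced residue
    exists in the topology.  Result is independent of config key order.
    """
    config = _normalise_config(region_config)
    sets: dict[str, frozenset[int]] = {}
    for name in sorted(config):
        sets[name] = _resolve_ranges(topology, name, config[name])

    # Validate disjointness among domains and among CDR loops
    for group in (DOMAIN_NAMES, LIGHT_CDRS + HEAVY_CDRS + DE_LOOPS):
        present = [n for n in group if n in sets]
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                if sets[a] & sets[b]:
                    raise RegionError(f"regions {a!r} and {b!r} overlap")
    # CDRs must sit inside their domain
    for cdr, domain in CDR_TO_DOMAIN.items():
        if cdr in sets:
            if domain not in sets:
                raise RegionError(f"{cdr!r} requires domain {domain!r} to be defined")
            if not sets[cdr] <= sets[domain]:
                stray = next(iter(sets[cdr] - sets[domain]))
                raise RegionError(
                    f"{cdr!r} is not contained in {domain!r} "
                    f"(residue {topology.residues[stray]})"
                )

    # Default switch regions when constant domains are present
    if "switch_L" not in sets and "VL" in sets and "CL" in sets:
        sets["switch_L"] = _default_switch(topology, sets["VL"], sets["CL"])
    if "switch_H" not in sets and "VH" in sets and "CH1" in sets:
        sets["switch_H"] = _default_switch(topology, sets["VH"], sets["CH1"])

    return AntibodyRegions(sets=sets)
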