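"""Multi-model PDB I/O and atom-group selection.

A :class:`StructureEnsemble` is the package's in-memory trajectory: a fixed
:class:`Topology` (atoms with chain, residue and mass metadata) plus an
``(n_frames, n_atoms, 3)`` coordinate array in Angstrom.  Ensembles are
exchanged on disk as multi-model PDB files (``MODEL``/``ENDMDL`` blocks),
the lowest-common-denominator trajectory format that every structural tool
can read.

Residue numbers are taken verbatim from the source file (here: UniProt
numbering for the cathepsin presets) and never renumbered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .elements import element_from_atom_name, is_hydrogen, mass_of
from .errors import FormatError, InputError, SelectionError

__all__ = [
    "AtomRecord",
    "Topology",
    "StructureEnsemble",
    "AtomSelection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "parse_selection_config",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``residue_number`` keeps the 1-based numbering written in the source
    file; ``atom_index`` is the 0-based ordinal within the topology.
    """

    atom_index: int
    atom_name: str
    element: str
    chain_id: str
    residue_number: int
    residue_name: str
    mass: float
    is_heavy: bool

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InputError(f"atom {self.atom_index}: mass must be positive")
        if self.is_heavy == is_hydrogen(self.element):
            raise InputError(
                f"atom {self.atom_index}: is_heavy inconsistent with element "
                f"{self.element!r}"
            )


@dataclass
class Topology:
    """Ordered atom list plus the ordered set of chain identifiers."""

    atoms: list[AtomRecord]
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError("topology must contain at least one atom")
        for i, atom in enumerate(self.atoms):
            if atom.atom_index != i:
                raise InputError("atom_index values must be consecutive from 0")
        if not self.chain_ids:
            seen: dict[str, None] = {}
            for atom in self.atoms:
                seen.setdefault(atom.chain_id, None)
            self.chain_ids = list(seen)
        missing = {a.chain_id for a in self.atoms} - set(self.chain_ids)
        if missing:
            raise InputError(f"chain_ids missing chains {sorted(missing)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def residues(self) -> set[tuple[str, int]]:
        """Set of (chain_id, residue_number) present in the topology."""
        return {(a.chain_id, a.residue_number) for a in self.atoms}


@dataclass
class StructureEnsemble:
    """Topology plus an ordered stack of coordinate frames (Angstrom).

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)``; ``frame_ids`` are
    the MODEL serial numbers of the source file (1-based by convention).
    """

    topology: Topology
    coordinates: np.ndarray
    frame_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InputError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise InputError("ensemble must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise InputError("coordinate atom count does not match topology")
        if not np.all(np.isfinite(self.coordinates)):
            raise InputError("coordinates contain non-finite values")
        if len(self.frame_ids) != self.coordinates.shape[0]:
            raise InputError("frame_ids length does not match frame count")
        if len(self.frame_ids) > 1 and not np.all(np.diff(self.frame_ids) > 0):
            raise InputError("frame_ids must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def frames(self) -> list[np.ndarray]:
        return [self.coordinates[i] for i in range(self.n_frames)]

    def subset(self, frame_positions: Sequence[int]) -> "StructureEnsemble":
        """New ensemble restricted to the given frame positions (0-based)."""
        pos = np.asarray(frame_positions, dtype=int)
        if pos.size == 0:
            raise InputError("frame subset must not be empty")
        return StructureEnsemble(
            topology=self.topology,
            coordinates=self.coordinates[pos],
            frame_ids=self.frame_ids[pos],
        )


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, duplicate-free list of 0-based atom indices with a label."""

    atom_indices: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise SelectionError(f"selection {self.label!r} is empty")
        idx = np.asarray(self.atom_indices)
        if len(np.unique(idx)) != len(idx) or not np.all(np.diff(idx) > 0):
            raise SelectionError(
                f"selection {self.label!r}: indices must be ascending and unique"
            )

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading/writing
#
# The parser is intentionally minimal and strict: fixed-column ATOM/HETATM
# records, MODEL/ENDMDL framing, altLoc ' '/'A' kept, insertion codes
# rejected (trajectories, unlike crystal structures, should not carry them).
# ---------------------------------------------------------------------------

_ATOM_RE = re.compile(r"^(ATOM  |HETATM)")


def _parse_atom_line(line: str, lineno: int):
    # PDB fixed columns (0-based slices)
    try:
        name = line[12:16]
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: malformed ATOM record") from exc
    if icode not in (" ", ""):
        raise FormatError(
            f"line {lineno}: insertion code {icode!r} not supported in ensembles"
        )
    if altloc not in (" ", "A", ""):
        return None  # keep only the primary alternate location
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = element_from_atom_name(name)
    return name.strip(), resname, chain, resseq, element.upper(), (x, y, z)


def read_multimodel_pdb(path: str | Path) -> StructureEnsemble:
    """Read a (multi-)model PDB file into a :class:`StructureEnsemble`.

    Each ``MODEL`` block becomes one frame; a file without MODEL records is
    a single implicit model with frame id 1.  The topology is taken from
    the first model; later models must have the same atom count.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"trajectory file not found: {path}")

    frames: list[list[tuple[float, float, float]]] = []
    frame_ids: list[int] = []
    meta: list[tuple[str, str, str, int, str]] = []
    current: list[tuple[float, float, float]] | None = None
    current_id: int | None = None
    in_first = True
    saw_model = False

    def _close_model() -> None:
        nonlocal current, current_id, in_first
        if current is None:
            return
        if frames and len(current) != len(meta):
            raise FormatError(
                f"MODEL {current_id}: has {len(current)} atoms, "
                f"expected {len(meta)}"
            )
        frames.append(current)
        frame_ids.append(current_id if current_id is not None else 1)
        current = None
        current_id = None
        in_first = False

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                _close_model()
                try:
                    current_id = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    current_id = len(frames) + 1
                current = []
            elif rec == "ENDMDL":
                _close_model()
            elif _ATOM_RE.match(line):
                parsed = _parse_atom_line(line, lineno)
                if parsed is None:
                    continue
                name, resname, chain, resseq, element, xyz = parsed
                if current is None:
                    if saw_model:
                        raise FormatError(
                            f"line {lineno}: ATOM record outside MODEL block"
                        )
                    current = []
                    current_id = 1
                if in_first and not frames:
                    meta.append((name, resname, chain, resseq, element))
                current.append(xyz)
    _close_model()

    if not frames:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=name,
            element=element,
            chain_id=chain,
            residue_number=resseq,
            residue_name=resname,
            mass=mass_of(element),
            is_heavy=not is_hydrogen(element),
        )
        for i, (name, resname, chain, resseq, element) in enumerate(meta)
    ]
    return StructureEnsemble(
        topology=Topology(atoms=atoms),
        coordinates=np.array(frames, dtype=float),
        frame_ids=np.array(frame_ids, dtype=int),
    )


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14, two-letter in column 13.
    if len(element) >= 2 or len(name) >= 4:
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)[:4]


def write_multimodel_pdb(
    ensemble: StructureEnsemble,
    frame_subset: Sequence[int],
    path: str | Path,
) -> Path:
    """Write selected frames (0-based positions) as a multi-model PDB.

    Output uses MODEL/ENDMDL framing with the ensemble's frame ids as MODEL
    serial numbers, TER records between chains and a final END.
    Coordinates are written to 3 decimals (PDB precision).
    """
    if len(frame_subset) == 0:
        raise InputError("frame_subset must not be empty")
    pos = np.asarray(frame_subset, dtype=int)
    if pos.min() < 0 or pos.max() >= ensemble.n_frames:
        raise InputError("frame_subset positions out of range")

    path = Path(path)
    top = ensemble.topology
    lines: list[str] = []
    for p in pos:
        lines.append(f"MODEL     {int(ensemble.frame_ids[p]):4d}")
        serial = 0
        prev_chain: str | None = None
        for atom, (x, y, z) in zip(top.atoms, ensemble.coordinates[p]):
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            serial += 1
            lines.append(
                "ATOM  {serial:5d} {name}{alt}{res:<3s} {chain}{resseq:4d}{icode}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                    serial=serial,
                    name=_format_atom_name(atom.atom_name, atom.element),
                    alt=" ",
                    res=atom.residue_name[:3],
                    chain=atom.chain_id[:1],
                    resseq=atom.residue_number,
                    icode=" ",
                    x=x,
                    y=y,
                    z=z,
                    occ=1.00,
                    b=0.00,
                    elem=atom.element[:2],
                )
            )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def select_atoms(
    topology: Topology,
    chain: str,
    residue_numbers: Iterable[int],
    heavy_only: bool = True,
    label: str | None = None,
) -> AtomSelection:
    """Select atoms of ``chain`` whose residue number is in ``residue_numbers``.

    With ``heavy_only`` (the default) hydrogens are excluded, which is the
    convention used throughout the contact and centre-of-mass analyses.
    Raises :class:`SelectionError` if nothing matches.
    """
    wanted = set(residue_numbers)
    if not wanted:
        raise SelectionError("residue_numbers must not be empty")
    if chain not in topology.chain_ids:
        raise SelectionError(
            f"chain {chain!r} not in topology (chains: {topology.chain_ids})"
        )
    indices = tuple(
        a.atom_index
        for a in topology.atoms
        if a.chain_id == chain
        and a.residue_number in wanted
        and (a.is_heavy or not heavy_only)
    )
    if not indices:
        raise SelectionError(
            f"selection resolved to zero atoms: chain {chain!r}, "
            f"residues {sorted(wanted)}"
        )
    if label is None:
        label = f"{chain}:{_compact_ranges(sorted(wanted))}"
    return AtomSelection(atom_indices=indices, label=label)


def _compact_ranges(numbers: Sequence[int]) -> str:
    parts: list[str] = []
    start = prev = numbers[0]
    for n in list(numbers[1:]) + [None]:  # type: ignore[list-item]
        if n is not None and n == prev + 1:
            prev = n
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if n is not None:
            start = prev = n
    return ",".join(parts)


_GROUP_RE = re.compile(
    r"^group\.(?P<name>[\w-]+)\s*=\s*chain:(?P<chain>\S+)\s+"
    r"residues:(?P<residues>\S+)(?:\s+heavy_only:(?P<heavy>\S+))?\s*$"
)


def parse_residue_spec(spec: str) -> set[int]:
    """Parse ``"185-200"`` or ``"108,278,298"`` (mixes allowed) to a set."""
    result: set[int] = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token[1:]:  # allow negative start, though PDB rarely has one
            lo, hi = token.rsplit("-", 1) if not token.startswith("-") else (token, "")
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError as exc:
                raise InputError(f"bad residue range {token!r}") from exc
            if hi_i < lo_i:
                raise InputError(f"descending residue range {token!r}")
            result.update(range(lo_i, hi_i + 1))
        else:
            try:
                result.add(int(token))
            except ValueError as exc:
                raise InputError(f"bad residue number {token!r}") from exc
    if not result:
        raise InputError(f"residue spec {spec!r} resolved to nothing")
    return result


def parse_selection_config(path: str | Path) -> dict[str, dict]:
    """Read ``group.<name> = chain:<id> residues:<spec> heavy_only:<bool>`` lines.

    Blank lines and ``#`` comments are ignored.  Returns a mapping from group
    name to ``{"chain": ..., "residues": set, "heavy_only": bool}``.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"selection config not found: {path}")
    groups: dict[str, dict] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _GROUP_RE.match(line)
        if m is None:
            raise FormatError(f"{path}:{lineno}: unrecognised config line: {line!r}")
        heavy = (m.group("heavy") or "true").lower()
        if heavy not in ("true", "false", "yes", "no", "1", "0"):
            raise FormatError(f"{path}:{lineno}: bad heavy_only value {heavy!r}")
        groups[m.group("name")] = {
            "chain": m.group("chain"),
            "residues": parse_residue_spec(m.group("residues")),
            "heavy_only": heavy in ("true", "yes", "1"),
        }
    return groups
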