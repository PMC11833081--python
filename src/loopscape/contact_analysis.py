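"""Inter-chain atomic contacts, ensemble filtering and residue statistics.

A contact is two heavy atoms of different selections closer than the
cutoff (default 3.3 A, strict inequality).  Frame filters discard
structures without any inter-chain contact, or without a contact to a
designated site (e.g. the allosteric pocket residues).  Per-residue
statistics are frame-normalised: the mean number of partner residues a
residue touches per frame, which can exceed 1 when a residue binds several
partners simultaneously.

Two contact kernels are provided: a k-d tree spatial query (default for
large selections) and an exhaustive all-pairs kernel, which doubles as the
correctness oracle for the tree kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .ensemble_io import AtomSelection, StructureEnsemble
from .errors import InputError
from .presets import DEFAULT_CONTACT_CUTOFF

__all__ = [
    "ContactSeries",
    "FrameFilter",
    "ContactStatistics",
    "detect_contacts",
    "filter_frames_any_contact",
    "filter_frames_site_contact",
    "residue_contact_statistics",
    "export_contact_network",
]

# Below this many atom pairs the exhaustive kernel is at least as fast as
# building a tree, so it is used directly.
_BRUTE_FORCE_LIMIT = 500 * 500

Residue = tuple[str, int]  # (chain_id, residue_number)
ResiduePair = tuple[Residue, Residue]


@dataclass
class ContactSeries:
    """Per-frame inter-selection atom contacts and their residue projection.

    ``atom_pairs[i]`` lists (atom_a, atom_b) global index pairs in contact
    in frame i; ``residue_pairs[i]`` is the deduplicated projection onto
    ((chain_a, res_a), (chain_b, res_b)) pairs.
    """

    atom_pairs: list[list[tuple[int, int]]]
    residue_pairs: list[list[ResiduePair]]
    cutoff: float
    frame_ids: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    topology_residues: frozenset[Residue] = field(default_factory=frozenset)

    @property
    def n_frames(self) -> int:
        return len(self.atom_pairs)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class FrameFilter:
    """Boolean keep-mask over frames with a human-readable rule."""

    keep: np.ndarray
    rule: str
    n_kept: int = -1

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.n_kept = int(np.count_nonzero(self.keep))

    def positions(self) -> np.ndarray:
        return np.flatnonzero(self.keep)

    def __and__(self, other: "FrameFilter") -> "FrameFilter":
        if len(self.keep) != len(other.keep):
            raise InputError("cannot AND filters of different lengths")
        return FrameFilter(
            keep=self.keep & other.keep, rule=f"({self.rule}) AND ({other.rule})"
        )


@dataclass
class ContactStatistics:
    """Frame-normalised residue contact statistics.

    ``per_residue`` maps (chain, residue_number) to the mean number of
    residue-pair contacts per frame involving that residue (may exceed 1).
    ``per_pair`` maps a residue pair to the fraction of frames in which it
    is in contact (in [0, 1]).
    """

    per_residue: dict[Residue, float]
    per_pair: dict[ResiduePair, float]
    n_frames: int


def _contacts_brute(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> np.ndarray:
    """All (i, j) with ||a_i - b_j|| < cutoff, by exhaustive enumeration."""
    d = cdist(coords_a, coords_b)
    return np.argwhere(d < cutoff)


def _contacts_tree(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> np.ndarray:
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    # query_pairs-style sparse result; strict inequality enforced below
    pairs = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff, output_type="coo_matrix")
    mask = pairs.data < cutoff
    out = np.column_stack([pairs.row[mask], pairs.col[mask]])
    # canonical ordering for reproducibility
    if len(out):
        out = out[np.lexsort((out[:, 1], out[:, 0]))]
    return out


def _heavy_indices(ensemble: StructureEnsemble, sel: AtomSelection) -> np.ndarray:
    heavy = ensemble.topology.heavy_mask
    idx = sel.indices
    return idx[heavy[idx]]


def detect_contacts(
    ensemble: StructureEnsemble,
    selection_a: AtomSelection,
    selection_b: AtomSelection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    kernel: str = "auto",
) -> ContactSeries:
    """Find all heavy-atom contacts between two selections in every frame.

    Parameters
    ----------
    kernel:
        ``"auto"`` picks the exhaustive kernel for small selections and a
        k-d tree query otherwise; ``"brute"`` and ``"tree"`` force one.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if kernel not in ("auto", "brute", "tree"):
        raise InputError(f"unknown kernel {kernel!r}")
    ia = _heavy_indices(ensemble, selection_a)
    ib = _heavy_indices(ensemble, selection_b)
    if ia.size == 0 or ib.size == 0:
        raise InputError("a selection has no heavy atoms")
    if np.intersect1d(ia, ib).size:
        raise InputError("selections must be disjoint")

    if kernel == "auto":
        kernel = "brute" if ia.size * ib.size <= _BRUTE_FORCE_LIMIT else "tree"
    find = _contacts_brute if kernel == "brute" else _contacts_tree

    atoms = ensemble.topology.atoms
    res_of = {i: (atoms[i].chain_id, atoms[i].residue_number) for i in np.concatenate([ia, ib])}

    atom_pairs: list[list[tuple[int, int]]] = []
    residue_pairs: list[list[ResiduePair]] = []
    for f in range(ensemble.n_frames):
        local = find(ensemble.coordinates[f, ia], ensemble.coordinates[f, ib], cutoff)
        pairs = [(int(ia[i]), int(ib[j])) for i, j in local]
        pairs.sort()
        atom_pairs.append(pairs)
        rp = sorted({(res_of[a], res_of[b]) for a, b in pairs})
        residue_pairs.append(rp)

    return ContactSeries(
        atom_pairs=atom_pairs,
        residue_pairs=residue_pairs,
        cutoff=float(cutoff),
        frame_ids=ensemble.frame_ids.copy(),
        label_a=selection_a.label,
        label_b=selection_b.label,
        topology_residues=frozenset(ensemble.topology.residues()),
    )


def filter_frames_any_contact(series: ContactSeries) -> FrameFilter:
    """Keep frames with at least one inter-selection contact."""
    if series.n_frames == 0:
        raise InputError("contact series is empty")
    keep = np.array([len(p) > 0 for p in series.atom_pairs], dtype=bool)
    return FrameFilter(keep=keep, rule=f"any contact < {series.cutoff} A")


def filter_frames_site_contact(
    series: ContactSeries, site_residues: set[Residue]
) -> FrameFilter:
    """Keep frames with a contact whose enzyme-side residue is in the site.

    ``site_residues`` is a set of (chain_id, residue_number); membership is
    checked against either end of each residue-pair contact, so the site
    may live on either selection's chain.
    """
    if not site_residues:
        raise InputError("site_residues must not be empty")
    if series.n_frames == 0:
        raise InputError("contact series is empty")
    site = {(str(c), int(r)) for c, r in site_residues}
    if series.topology_residues:
        missing = site - set(series.topology_residues)
        if missing:
            raise InputError(
                f"site residues absent from topology: {sorted(missing)}"
            )
    keep = np.array(
        [any(ra in site or rb in site for ra, rb in rp) for rp in series.residue_pairs],
        dtype=bool,
    )
    label = ",".join(f"{c}:{r}" for c, r in sorted(site))
    return FrameFilter(keep=keep, rule=f"site contact [{label}] < {series.cutoff} A")


def residue_contact_statistics(series: ContactSeries) -> ContactStatistics:
    """Frame-normalised contact counts per residue and per residue pair.

    Per residue: total residue-pair contacts involving it across frames,
    divided by the number of frames.  Per pair: fraction of frames in which
    the pair is in contact.
    """
    if series.n_frames == 0:
        raise InputError("contact series is empty")
    n = series.n_frames
    residue_counts: dict[Residue, int] = {}
    pair_counts: dict[ResiduePair, int] = {}
    for rp in series.residue_pairs:
        for ra, rb in rp:
            residue_counts[ra] = residue_counts.get(ra, 0) + 1
            residue_counts[rb] = residue_counts.get(rb, 0) + 1
            pair_counts[(ra, rb)] = pair_counts.get((ra, rb), 0) + 1
    return ContactStatistics(
        per_residue={r: c / n for r, c in residue_counts.items()},
        per_pair={p: c / n for p, c in pair_counts.items()},
        n_frames=n,
    )


def export_contact_network(stats: ContactStatistics, path: str | Path) -> Path:
    """Write the contact network as delimited edge and node tables.

    The edge table (``path``) has columns chain_a, residue_a, chain_b,
    residue_b, contact_fraction, sorted by descending fraction with ties
    broken by ascending (residue_a, residue_b).  The node table, at
    ``<stem>.nodes<suffix>`` next to it, carries the per-residue values.
    """
    if not stats.per_residue and not stats.per_pair:
        raise InputError("contact statistics are empty")
    path = Path(path)
    edges = pd.DataFrame(
        [
            {
                "chain_a": ra[0],
                "residue_a": ra[1],
                "chain_b": rb[0],
                "residue_b": rb[1],
                "contact_fraction": frac,
            }
            for (ra, rb), frac in stats.per_pair.items()
        ]
    )
    if len(edges):
        edges = edges.sort_values(
            ["contact_fraction", "residue_a", "residue_b"],
            ascending=[False, True, True],
            kind="mergesort",
        )
    edges.to_csv(path, sep="\t", index=False, float_format="%.6f")

    nodes = pd.DataFrame(
        [
            {"chain": r[0], "residue": r[1], "mean_contacts_per_frame": v}
            for r, v in sorted(stats.per_residue.items())
        ]
    )
    node_path = path.with_name(path.stem + ".nodes" + path.suffix)
    nodes.to_csv(node_path, sep="\t", index=False, float_format="%.6f")
    return path
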