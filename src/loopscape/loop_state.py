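"""Occluding-loop open/closed state analysis.

The reaction coordinate is the Euclidean distance between the mass-weighted
centroids (COM) of two atom groups — canonically the occluding loop
(residues 185-200) and the active-site residues (108, 278, 298) of
cathepsin B.  Frames with COM distance at or below a threshold (default
16.5 A) are *closed*; strictly above, *open*.  The boundary is inclusive on
the closed side.

COM uses standard atomic weights; the shipped presets select heavy atoms
only, which keeps results independent of how the generating MD engine
treated hydrogen masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import AtomSelection, StructureEnsemble
from .errors import InputError
from .presets import DEFAULT_STATE_THRESHOLD

__all__ = [
    "DistanceTrace",
    "StateSeries",
    "ThresholdScan",
    "com_distance_trace",
    "classify_states",
    "threshold_scan",
    "open_fraction_fold_change",
]

CLOSED = "closed"
OPEN = "open"


@dataclass
class DistanceTrace:
    """Per-frame COM distance (Angstrom) between two labelled groups."""

    values: np.ndarray
    frame_ids: np.ndarray
    group_a_label: str
    group_b_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if self.values.ndim != 1 or len(self.values) != len(self.frame_ids):
            raise InputError("values and frame_ids must be 1D and equal length")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StateSeries:
    """Open/closed labelling of a distance trace at a fixed threshold."""

    labels: np.ndarray  # array of "closed"/"open"
    threshold: float
    fraction_open: float
    fraction_closed: float
    frame_ids: np.ndarray

    @property
    def n_open(self) -> int:
        return int(np.sum(self.labels == OPEN))

    @property
    def n_closed(self) -> int:
        return int(np.sum(self.labels == CLOSED))


@dataclass
class ThresholdScan:
    """Closed fraction as a function of the distance threshold (an ECDF)."""

    thresholds: np.ndarray
    closed_fraction: np.ndarray

    @property
    def open_fraction(self) -> np.ndarray:
        return 1.0 - self.closed_fraction


def com_distance_trace(
    ensemble: StructureEnsemble,
    group_a: AtomSelection,
    group_b: AtomSelection,
) -> DistanceTrace:
    """Per-frame distance between the mass-weighted centroids of two groups.

    The selections must be disjoint: a shared atom would make the COM
    separation ill-defined as a distance between two bodies.
    """
    ia, ib = group_a.indices, group_b.indices
    n_atoms = ensemble.topology.n_atoms
    if ia.max() >= n_atoms or ib.max() >= n_atoms:
        raise InputError("selection indices exceed topology size")
    if np.intersect1d(ia, ib).size:
        raise InputError(
            f"selections {group_a.label!r} and {group_b.label!r} overlap; "
            "COM distance requires disjoint groups"
        )
    masses = ensemble.topology.masses
    wa = masses[ia] / masses[ia].sum()
    wb = masses[ib] / masses[ib].sum()
    com_a = np.einsum("fij,i->fj", ensemble.coordinates[:, ia, :], wa)
    com_b = np.einsum("fij,i->fj", ensemble.coordinates[:, ib, :], wb)
    values = np.linalg.norm(com_a - com_b, axis=1)
    return DistanceTrace(
        values=values,
        frame_ids=ensemble.frame_ids.copy(),
        group_a_label=group_a.label,
        group_b_label=group_b.label,
    )


def classify_states(
    trace: DistanceTrace, threshold: float = DEFAULT_STATE_THRESHOLD
) -> StateSeries:
    """Label frames closed (distance <= threshold) or open (> threshold)."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    if len(trace) == 0:
        raise InputError("cannot classify an empty trace")
    closed = trace.values <= threshold
    labels = np.where(closed, CLOSED, OPEN)
    fraction_closed = float(np.count_nonzero(closed)) / len(trace)
    return StateSeries(
        labels=labels,
        threshold=float(threshold),
        fraction_open=1.0 - fraction_closed,
        fraction_closed=fraction_closed,
        frame_ids=trace.frame_ids.copy(),
    )


def threshold_scan(trace: DistanceTrace, grid: np.ndarray) -> ThresholdScan:
    """Closed fraction at each grid threshold: the ECDF of the distances.

    ``closed_fraction[t]`` is the proportion of frames with distance <= t,
    consistent with :func:`classify_states` at every grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("grid must not be empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InputError("grid must be strictly ascending")
    if len(trace) == 0:
        raise InputError("cannot scan an empty trace")
    sorted_vals = np.sort(trace.values)
    counts = np.searchsorted(sorted_vals, grid, side="right")
    return ThresholdScan(
        thresholds=grid, closed_fraction=counts / len(trace)
    )


def default_scan_grid() -> np.ndarray:
    """Default threshold grid: 12 to 24 Angstrom in 0.1 A steps."""
    return np.round(np.arange(120, 241) * 0.1, 10)


def open_fraction_fold_change(
    case_fractions, reference_fractions
) -> float:
    """Ratio of mean open fractions: mean(case) / mean(reference).

    This is the fold change in active (open) states between a set of
    perturbed conditions and a set of reference conditions, computed as the
    ratio of group means.
    """
    case = np.asarray(case_fractions, dtype=float)
    ref = np.asarray(reference_fractions, dtype=float)
    if case.size == 0 or ref.size == 0:
        raise InputError("both fraction lists must be non-empty")
    for arr, name in ((case, "case"), (ref, "reference")):
        if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
            raise InputError(f"{name} fractions must lie in [0, 1]")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise InputError("reference mean open fraction is zero; ratio undefined")
    return float(case.mean() / ref_mean)
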