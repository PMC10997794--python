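"""Axis traces and recombination-focus densities.

Chromosome axes in a spread nucleus are represented as polylines traced
over the axis-marker channel, each flagged synapsed or unsynapsed. DMC1
and RPA2 foci are merged into recombination foci when the center of one
lies inside the signal of the other, assigned to the nearest axis trace,
and counted per µm of synapsed vs unsynapsed axis. The per-cell
unsynapsed-to-synapsed density ratio is the readout for whether DSB
activity is topped up on late-synapsing axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .detect import Focus

__all__ = [
    "AxisTrace",
    "RecombinationFocus",
    "DensityResult",
    "polyline_length",
    "merge_two_channel_foci",
    "assign_to_axis",
    "compute_density",
]


@dataclass(frozen=True)
class AxisTrace:
    """A polyline axis segment in pixel coordinates.

    ``vertices`` is an (n, 2) float array of (row, col) positions.
    A single-vertex trace is a degenerate point of length zero.
    """

    segment_id: int
    vertices: np.ndarray
    synapsed: bool

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
            raise ValueError("vertices must be an (n, 2) array, n >= 1")
        object.__setattr__(self, "vertices", v)

    def length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def length_um(self, pixel_size: float) -> float:
        return polyline_length(self, pixel_size)


def polyline_length(trace: AxisTrace, pixel_size: float) -> float:
    """Physical length in µm: sum of Euclidean inter-vertex distances x pixel size."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    return trace.length_px() * pixel_size


@dataclass(frozen=True)
class RecombinationFocus:
    """A merged DMC1/RPA2 recombination focus.

    Holds the ids of member foci per channel (one of them may be None
    for a singleton) and a representative centroid in pixels. When a
    DMC1 and an RPA2 focus merge, the representative centroid is the
    midpoint of the two member centroids.
    """

    dmc1_id: int | None
    rpa2_id: int | None
    centroid: tuple[float, float]


def _centroid_pixel(f: Focus) -> tuple[int, int]:
    r, c = f.centroid
    return (int(round(r)), int(round(c)))


def merge_two_channel_foci(
    dmc1: list[Focus], rpa2: list[Focus]
) -> list[RecombinationFocus]:
    """Merge coincident DMC1 and RPA2 foci into single recombination foci.

    A DMC1 and an RPA2 focus merge iff the centroid pixel of either
    lies inside the other's pixel set — touching without center overlap
    does not merge. Candidate pairs are resolved greedily by descending
    pixel-overlap area (ties by lower dmc1 id, then lower rpa2 id), each
    focus merging at most once; unmerged foci pass through as
    singletons, so the output count is |dmc1| + |rpa2| - n_merged_pairs.
    """
    rpa_sets = {f.focus_id: f.pixel_set() for f in rpa2}
    dmc_sets = {f.focus_id: f.pixel_set() for f in dmc1}
    candidates = []
    for fd in dmc1:
        cd = _centroid_pixel(fd)
        dset = dmc_sets[fd.focus_id]
        for fr in rpa2:
            cr = _centroid_pixel(fr)
            rset = rpa_sets[fr.focus_id]
            if cd in rset or cr in dset:
                ov = len(dset & rset)
                candidates.append((-ov, fd.focus_id, fr.focus_id, fd, fr))
    candidates.sort(key=lambda t: t[:3])
    used_d: set[int] = set()
    used_r: set[int] = set()
    out: list[RecombinationFocus] = []
    for _, did, rid, fd, fr in candidates:
        if did in used_d or rid in used_r:
            continue
        used_d.add(did)
        used_r.add(rid)
        (r1, c1), (r2, c2) = fd.centroid, fr.centroid
        out.append(RecombinationFocus(did, rid, ((r1 + r2) / 2, (c1 + c2) / 2)))
    for fd in dmc1:
        if fd.focus_id not in used_d:
            out.append(RecombinationFocus(fd.focus_id, None, fd.centroid))
    for fr in rpa2:
        if fr.focus_id not in used_r:
            out.append(RecombinationFocus(None, fr.focus_id, fr.centroid))
    return out


def assign_to_axis(
    foci: list[RecombinationFocus],
    traces: list[AxisTrace],
    max_distance: float,
    pixel_size: float,
) -> list[int | None]:
    """Assign each focus to the nearest axis trace within ``max_distance`` (µm).

    Distance is point-to-polyline in physical units. A focus farther
    than ``max_distance`` from every trace is unassigned (None). Exact
    distance ties go to the lower segment_id.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    ordered = sorted(traces, key=lambda t: t.segment_id)
    geoms = [
        (t.segment_id, LineString(t.vertices) if len(t.vertices) > 1 else Point(t.vertices[0]))
        for t in ordered
    ]
    out: list[int | None] = []
    for f in foci:
        p = Point(f.centroid)
        best_id, best_d = None, np.inf
        for sid, g in geoms:
            d = g.distance(p) * pixel_size
            if d < best_d:  # first (lowest id) wins ties
                best_d, best_id = d, sid
        out.append(best_id if best_d <= max_distance else None)
    return out


@dataclass(frozen=True)
class DensityResult:
    """Per-cell recombination-focus density summary.

    Densities are foci per µm of axis in each synapsis class. The
    unsynapsed-to-synapsed ratio is NaN (undefined, not infinite) when
    the synapsed density is zero. ``synapsis_class`` is ">70%" when
    strictly more than 70% of total axis length is synapsed, else
    "<=70%".
    """

    cell_id: str
    n_syn: int
    n_unsyn: int
    n_unassigned: int
    length_syn: float
    length_unsyn: float
    density_syn: float
    density_unsyn: float
    ratio_unsyn_to_syn: float
    percent_synapsed: float
    synapsis_class: str


def compute_density(
    foci: list[RecombinationFocus],
    traces: list[AxisTrace],
    pixel_size: float,
    max_distance: float = 0.3,
    cell_id: str = "",
) -> DensityResult:
    """Count assigned foci per µm of synapsed and unsynapsed axis.

    Each focus is assigned to its nearest trace within ``max_distance``
    µm and inherits that trace's synapsis flag; densities divide class
    counts by total class length. A class with zero total length has an
    undefined (NaN) density, and the ratio is NaN whenever the synapsed
    density is zero or undefined — never infinite.
    """
    if not traces:
        raise ValueError("at least one axis trace is required")
    trace_by_id = {t.segment_id: t for t in traces}
    assign = assign_to_axis(foci, traces, max_distance, pixel_size)
    n_syn = sum(1 for a in assign if a is not None and trace_by_id[a].synapsed)
    n_unsyn = sum(1 for a in assign if a is not None and not trace_by_id[a].synapsed)
    n_un = sum(1 for a in assign if a is None)
    l_syn = sum(polyline_length(t, pixel_size) for t in traces if t.synapsed)
    l_unsyn = sum(polyline_length(t, pixel_size) for t in traces if not t.synapsed)
    total = l_syn + l_unsyn
    if total <= 0:
        raise ValueError("total axis length is zero")
    d_syn = n_syn / l_syn if l_syn > 0 else float("nan")
    d_unsyn = n_unsyn / l_unsyn if l_unsyn > 0 else float("nan")
    if np.isfinite(d_syn) and d_syn > 0 and np.isfinite(d_unsyn):
        ratio = d_unsyn / d_syn
    else:
        ratio = float("nan")
    pct = 100.0 * l_syn / total
    return DensityResult(
        cell_id=cell_id,
        n_syn=n_syn,
        n_unsyn=n_unsyn,
        n_unassigned=n_un,
        length_syn=l_syn,
        length_unsyn=l_unsyn,
        density_syn=d_syn if np.isfinite(d_syn) else float("nan"),
        density_unsyn=d_unsyn if np.isfinite(d_unsyn) else float("nan"),
        ratio_unsyn_to_syn=ratio,
        percent_synapsed=pct,
        synapsis_class=">70%" if pct > 70.0 else "<=70%",
    )
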