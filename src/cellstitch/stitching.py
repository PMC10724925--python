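"""Optimal-transport stitching of adjacent Z-layers into 3D cell instances.

Each layer is summarized as a discrete distribution of label masses (pixel
count of each label, background included, divided by the layer's pixel
count).  Two adjacent layers are coupled by exact optimal transport under the
cost ``C[x, y] = 1 - J(x, y)``, where ``J`` is the Jaccard index of the two
labels' pixel supports at identical (Y, X) coordinates.  Overlap — not
centroid distance — is what identifies the same cell across layers: densely
packed cells routinely have a nearer neighbour's centroid in the next layer.

From the solved plan, each source cell traces to the target label receiving
most of its mass; each target cell is claimed by the tracer of least cost, or
declared a new cell when nothing traces to it.  Because distinct cells
stacked along Z can also overlap heavily, a matched pair is additionally put
to a vote: every pixel of the target cell compares its labels across the two
layers in the orthogonal YZ- and XZ-plane masks, and the match is rejected
when the fraction of disagreeing votes reaches a threshold.

Stitching proceeds from the top layer down; cells confined to fewer than a
minimum number of layers (the residue of repaired over-segmentation) are
removed in a final pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cellstitch._transport import exact_transport
from cellstitch.volumes import LabelVolume, OrthogonalMasks

#: transported mass below this is treated as zero when tracing
_MASS_TOL = 1e-12


@dataclass(frozen=True)
class MassDistribution:
    """Label-mass proportions of one layer; background (label 0) comes first.

    ``masses[i]`` is the pixel count of ``labels[i]`` divided by the layer's
    total pixel count, so the masses sum to 1.  Background is always listed,
    possibly with mass 0.
    """

    labels: np.ndarray  # sorted, labels[0] == 0
    masses: np.ndarray

    def __post_init__(self):
        if self.labels[0] != 0:
            raise ValueError("background label 0 must be listed first")
        if abs(float(self.masses.sum()) - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")


@dataclass(frozen=True)
class CostMatrix:
    """``1 - Jaccard`` costs between the labels of two adjacent layers.

    Entry ``(i, j)`` compares the pixel support of ``row_labels[i]`` in the
    source layer with that of ``col_labels[j]`` in the target layer; it is 1
    exactly when the supports are disjoint.  Background occupies row/column 0.
    """

    entries: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    def row_index(self, label: int) -> int:
        i = int(np.searchsorted(self.row_labels, label))
        if i >= self.row_labels.size or self.row_labels[i] != label:
            raise KeyError(f"label {label} not a source label")
        return i

    def col_index(self, label: int) -> int:
        j = int(np.searchsorted(self.col_labels, label))
        if j >= self.col_labels.size or self.col_labels[j] != label:
            raise KeyError(f"label {label} not a target label")
        return j


@dataclass(frozen=True)
class TransportPlan:
    """An exact optimal coupling between two layers' mass distributions."""

    coupling: np.ndarray
    objective: float
    row_labels: np.ndarray
    col_labels: np.ndarray


@dataclass(frozen=True)
class TracingMap:
    """Which target label each source cell sends most of its mass to.

    ``mapping[x]`` is the argmax of the plan row of source cell ``x`` when
    that argmax is a foreground label with positive mass, else ``None``;
    ``preimages[y]`` collects the source cells tracing to ``y``.
    """

    mapping: dict
    preimages: dict


@dataclass(frozen=True)
class StitchConfig:
    """Tunable knobs of the stitching pass.

    rejection_threshold
        A matched pair is rejected (the target starts a new cell) when the
        fraction of rejecting orthogonal votes is at least this value.
        0.5 means majority rejection.
    use_orthogonal_vote
        When False, or when no orthogonal masks are supplied, every match is
        accepted as-is.
    min_layers_per_cell
        Cells spanning fewer distinct Z-layers are erased in the final pass.
    """

    rejection_threshold: float = 0.5
    use_orthogonal_vote: bool = True
    tie_rule: str = "lowest-label"
    min_layers_per_cell: int = 2

    def __post_init__(self):
        if not 0.0 <= self.rejection_threshold <= 1.0:
            raise ValueError("rejection_threshold must lie in [0, 1]")
        if self.tie_rule != "lowest-label":
            raise ValueError("only the 'lowest-label' tie rule is supported")
        if self.min_layers_per_cell < 1:
            raise ValueError("min_layers_per_cell must be >= 1")


@dataclass
class PairRecord:
    """Audit record of one target cell's stitching decision."""

    z: int
    target_label: int
    traced_source: int | None
    rejection_fraction: float | None
    assigned_label: int
    new_cell: bool


def _as_layer(layer) -> np.ndarray:
    arr = np.asarray(layer)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("a layer must be a non-empty 2D array")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("layers must be integer label images")
    return arr


def _layer_labels(arr: np.ndarray) -> np.ndarray:
    """Sorted labels of a layer with background 0 always present and first."""
    labels = np.unique(arr)
    if labels[0] != 0:
        labels = np.concatenate([[0], labels])
    return labels


def layer_distribution(layer) -> MassDistribution:
    """Proportion of the layer's pixels carried by each label."""
    arr = _as_layer(layer)
    labels = _layer_labels(arr)
    counts = np.zeros(labels.size, dtype=np.int64)
    present, n = np.unique(arr, return_counts=True)
    counts[np.searchsorted(labels, present)] = n
    return MassDistribution(labels=labels, masses=counts / arr.size)


def jaccard_cost(layer_z, layer_z1) -> CostMatrix:
    """``1 - Jaccard`` cost between all label pairs of two same-shape layers.

    The background row/column is computed by the same formula on the
    background supports.
    """
    a = _as_layer(layer_z)
    b = _as_layer(layer_z1)
    if a.shape != b.shape:
        raise ValueError(f"layer shapes differ: {a.shape} vs {b.shape}")
    la, lb = _layer_labels(a), _layer_labels(b)
    ia = np.searchsorted(la, a.ravel())
    ib = np.searchsorted(lb, b.ravel())
    inter = np.bincount(ia * lb.size + ib, minlength=la.size * lb.size)
    inter = inter.reshape(la.size, lb.size).astype(np.int64)
    size_a = inter.sum(axis=1)
    size_b = inter.sum(axis=0)
    union = size_a[:, None] + size_b[None, :] - inter
    jac = np.divide(inter, union, out=np.zeros_like(inter, dtype=float),
                    where=union > 0)
    return CostMatrix(entries=1.0 - jac, row_labels=la, col_labels=lb)


def solve_transport(P: MassDistribution, P1: MassDistribution,
                    C: CostMatrix) -> TransportPlan:
    """Exact optimal coupling with ``P`` and ``P1`` as marginals."""
    if not np.array_equal(P.labels, C.row_labels) or not np.array_equal(
            P1.labels, C.col_labels):
        raise ValueError("cost matrix labels do not match the distributions")
    coupling, objective = exact_transport(P.masses, P1.masses, C.entries)
    return TransportPlan(coupling=coupling, objective=objective,
                         row_labels=C.row_labels, col_labels=C.col_labels)


def trace_cells(plan: TransportPlan) -> TracingMap:
    """Trace each source cell to the target label receiving most of its mass.

    Ties are broken toward the lowest target label (column labels are sorted,
    so the first argmax wins).  A source whose argmax is the background
    column, or whose row carries no mass, traces to nothing.
    """
    mapping: dict = {}
    preimages: dict = {}
    for i, x in enumerate(plan.row_labels):
        if x == 0:
            continue
        row = plan.coupling[i]
        j = int(np.argmax(row))
        y = int(plan.col_labels[j])
        if row[j] <= _MASS_TOL or y == 0:
            mapping[int(x)] = None
        else:
            mapping[int(x)] = y
            preimages.setdefault(y, set()).add(int(x))
    return TracingMap(mapping=mapping, preimages=preimages)


def best_tracer(y: int, tracing: TracingMap, C: CostMatrix) -> int | None:
    """Least-cost source cell among those tracing to ``y``; None if there is
    none (``y`` is then a new cell).  Cost ties go to the lowest label."""
    candidates = sorted(tracing.preimages.get(int(y), ()))
    if not candidates:
        return None
    j = C.col_index(int(y))
    best, best_cost = None, np.inf
    for x in candidates:
        c = float(C.entries[C.row_index(x), j])
        if c < best_cost:
            best, best_cost = x, c
    return best


def rejection_fraction(y_pixels, z: int, ortho: OrthogonalMasks) -> float:
    """Fraction of orthogonal-mask votes rejecting a match at layers z, z+1.

    Every pixel ``(r, c)`` of the target cell (in layer ``z+1``) casts two
    votes: the YZ-plane at X = c rejects iff its labels at (z+1, r) and
    (z, r) differ, and the XZ-plane at Y = r rejects iff its labels at
    (z+1, c) and (z, c) differ.  Two background labels compare equal and so
    never reject.
    """
    pix = np.atleast_2d(np.asarray(list(y_pixels) if not isinstance(y_pixels, np.ndarray) else y_pixels))
    if pix.size == 0:
        raise ValueError("rejection vote needs at least one pixel")
    rr, cc = pix[:, 0], pix[:, 1]
    yz_reject = ortho.yz[cc, z + 1, rr] != ortho.yz[cc, z, rr]
    xz_reject = ortho.xz[rr, z + 1, cc] != ortho.xz[rr, z, cc]
    return float(yz_reject.sum() + xz_reject.sum()) / (2 * pix.shape[0])


def stitch_pair(relabeled_z, raw_z1, z: int, ortho: OrthogonalMasks | None,
                config: StitchConfig, next_label: int):
    """Relabel one raw layer consistently with the already-relabeled layer above.

    Returns ``(relabeled_z1, next_label, records)``.  Each foreground cell of
    ``raw_z1`` either inherits the global label of its accepted least-cost
    tracer or receives a fresh label (no tracer, or the orthogonal vote
    rejected the match).  A source cell can relabel at most one target cell,
    which is what repairs over-segmentation in the layer above.
    """
    rel = _as_layer(relabeled_z)
    raw = _as_layer(raw_z1)
    if rel.shape != raw.shape:
        raise ValueError("layer shapes differ")
    P = layer_distribution(rel)
    P1 = layer_distribution(raw)
    C = jaccard_cost(rel, raw)
    plan = solve_transport(P, P1, C)
    tracing = trace_cells(plan)

    out = np.zeros_like(raw, dtype=np.uint32)
    records = []
    vote = config.use_orthogonal_vote and ortho is not None
    for y in P1.labels[P1.labels > 0]:
        y = int(y)
        mask = raw == y
        x = best_tracer(y, tracing, C)
        frac = None
        # a tracer with cost 1 shares no pixels with y: its transported mass
        # merely passes through background, so y is a new cell regardless
        accepted = x is not None and (
            C.entries[C.row_index(x), C.col_index(y)] < 1.0 - 1e-12)
        if accepted and vote:
            frac = rejection_fraction(np.argwhere(mask), z, ortho)
            accepted = frac < config.rejection_threshold
        if accepted:
            label = int(x)
        else:
            label = int(next_label)
            next_label += 1
        out[mask] = label
        records.append(PairRecord(z=z, target_label=y, traced_source=x,
                                  rejection_fraction=frac,
                                  assigned_label=label,
                                  new_cell=not accepted))
    return out, next_label, records


def remove_isolated_cells(volume: LabelVolume, min_layers: int = 2) -> LabelVolume:
    """Erase cells spanning fewer than ``min_layers`` distinct Z-layers.

    Over-segmentation repair leaves the losing fragment unused by any later
    layer, so it survives only in isolated layers; this pass clears it.
    """
    data = volume.data.copy()
    spans: dict = {}
    for z in range(data.shape[0]):
        for lab in np.unique(data[z]):
            if lab:
                spans[int(lab)] = spans.get(int(lab), 0) + 1
    doomed = [lab for lab, n in spans.items() if n < min_layers]
    if doomed:
        data[np.isin(data, doomed)] = 0
    return LabelVolume(data)


def stitch_volume(z_masks: LabelVolume, ortho: OrthogonalMasks | None = None,
                  config: StitchConfig | None = None,
                  decision_log: list | None = None) -> LabelVolume:
    """Stitch independently labeled per-layer masks into a consistent volume.

    Layer 0's labels are mapped to fresh global labels preserving its
    partition; subsequent layers are processed top to bottom via
    :func:`stitch_pair`; finally cells confined to fewer than
    ``config.min_layers_per_cell`` layers are removed.

    ``decision_log``, when given, collects one :class:`PairRecord` per target
    cell across all layer pairs.
    """
    config = config or StitchConfig()
    data = z_masks.data
    if ortho is not None:
        ortho.check_compatible(data.shape)

    out = np.zeros_like(data, dtype=np.uint32)
    next_label = int(data.max()) + 1
    for lab in np.unique(data[0]):
        if lab:
            out[0][data[0] == lab] = next_label
            next_label += 1
    for z in range(data.shape[0] - 1):
        rel, next_label, records = stitch_pair(
            out[z], data[z + 1], z, ortho, config, next_label)
        out[z + 1] = rel
        if decision_log is not None:
            decision_log.extend(records)
    return remove_isolated_cells(LabelVolume(out), config.min_layers_per_cell)
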