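"""Per-object and per-cell condensate statistics.

Implements the quantities reported in condensate studies of this kind:
fraction of a channel's total cellular signal residing in segmented objects,
nucleocytoplasmic partition, per-object Pearson colocalisation between two
channels, object counts and physical sizes per cell, classification of
P-body protein content against local cytoplasmic background, and SG–P-body
docking events (contact within a configurable surface gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabelMap


def _as3d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    return a[None] if a.ndim == 2 else a


def percent_signal_in_objects(channel: np.ndarray, labels: LabelMap,
                              cell_mask: np.ndarray,
                              background: float | str = "none") -> float:
    """Percentage of total cellular signal located in segmented objects.

    ``100 · Σ(corrected signal in labelled voxels) / Σ(signal in the cell
    mask)``.  The background correction is applied to the object voxels only:
    ``"none"`` (default — the raw complement identity "inside + outside =
    100" then holds exactly), ``"mode"`` (subtract the modal non-object
    intensity of the cell, so the diffuse pool under the object masks does
    not count as condensate signal) or a numeric offset.  Raises on zero
    total cell signal.
    """
    vol = _as3d(channel).astype(np.float64)
    cm = _as3d(cell_mask).astype(bool)
    lab = labels.labels
    offset = 0.0
    if isinstance(background, str):
        if background == "mode":
            cyto = vol[cm & (lab == 0)]
            if cyto.size:
                hist, edges = np.histogram(cyto, bins=64)
                k = int(hist.argmax())
                offset = 0.5 * (edges[k] + edges[k + 1])
        elif background != "none":
            raise ValueError(f"unknown background mode {background!r}")
    else:
        offset = float(background)
    total = vol[cm].sum()
    if total <= 0:
        raise ValueError("zero total cell signal")
    inside = (vol[cm & (lab > 0)] - offset).sum()
    return float(100.0 * inside / total)


def nucleocytoplasmic_partition(channel: np.ndarray, nuclear_mask: np.ndarray,
                                cell_mask: np.ndarray) -> float:
    """Percent of total cellular signal in the cytoplasm (cell − nucleus)."""
    vol = _as3d(channel).astype(np.float64)
    nm, cm = _as3d(nuclear_mask).astype(bool), _as3d(cell_mask).astype(bool)
    if np.any(nm & ~cm):
        raise ValueError("nuclear mask extends outside the cell mask")
    total = vol[cm].sum()
    if total <= 0:
        raise ValueError("zero total cell signal")
    return float(100.0 * vol[cm & ~nm].sum() / total)


@dataclass
class ColocResult:
    """Pearson correlation between two channels over one object's voxels."""

    object_id: int
    r: float
    n_voxels: int
    defined: bool = True


def per_object_pearson(labels: LabelMap, channel_a: np.ndarray,
                       channel_b: np.ndarray) -> list[ColocResult]:
    """Pearson r between two channels within each object's voxel set.

    Objects in which either channel is constant get ``defined=False`` and
    ``r=nan`` and are excluded from summaries.  The correlation is invariant
    under positive affine rescaling of either channel.
    """
    a, b = _as3d(channel_a).astype(np.float64), _as3d(channel_b).astype(np.float64)
    lab = labels.labels
    out: list[ColocResult] = []
    for oid in range(1, labels.n_objects + 1):
        m = lab == oid
        va, vb = a[m], b[m]
        if va.std() == 0 or vb.std() == 0:
            out.append(ColocResult(oid, np.nan, int(m.sum()), defined=False))
            continue
        r = float(np.corrcoef(va, vb)[0, 1])
        out.append(ColocResult(oid, r, int(m.sum())))
    return out


def summarize_pearson(results: list[ColocResult]) -> dict:
    rs = np.array([c.r for c in results if c.defined])
    return {"n": int(rs.size), "mean_r": float(rs.mean()) if rs.size else np.nan,
            "sd_r": float(rs.std(ddof=1)) if rs.size > 1 else np.nan,
            "n_undefined": sum(not c.defined for c in results)}


def classify_body_content(labels: LabelMap, channel: np.ndarray,
                          cell_labels: np.ndarray,
                          object_cells: np.ndarray | None = None,
                          enrichment_factor: float = 1.5) -> pd.DataFrame:
    """Which P-bodies "contain" a protein, against local cytoplasmic background.

    An object is positive when its mean intensity exceeds
    ``enrichment_factor`` × the median non-object intensity of its cell.
    Returns a per-object table; the pooled percent positive is in
    ``df.attrs["percent_positive"]`` (nan, flagged, when there are no
    objects).
    """
    vol = _as3d(channel).astype(np.float64)
    cells = _as3d(cell_labels)
    lab = labels.labels
    n = labels.n_objects
    if object_cells is None and n:
        object_cells = ndimage.labeled_comprehension(
            cells, lab, np.arange(1, n + 1),
            lambda v: np.bincount(v.astype(int)).argmax(), int, 0)
    rows = []
    med_by_cell: dict[int, float] = {}
    for i, oid in enumerate(range(1, n + 1)):
        cid = int(object_cells[i])
        if cid not in med_by_cell:
            cyto = vol[(cells == cid) & (lab == 0)]
            med_by_cell[cid] = float(np.median(cyto)) if cyto.size else 0.0
        mean = float(vol[lab == oid].mean())
        rows.append({"label": oid, "cell_id": cid, "mean": mean,
                     "cell_background": med_by_cell[cid],
                     "positive": mean > enrichment_factor * med_by_cell[cid]})
    df = pd.DataFrame(rows, columns=["label", "cell_id", "mean",
                                     "cell_background", "positive"])
    df.attrs["enrichment_factor"] = enrichment_factor
    df.attrs["percent_positive"] = (
        float(100.0 * df["positive"].mean()) if len(df) else np.nan)
    return df


def docking_events(sg_labels: LabelMap, pb_labels: LabelMap,
                   max_gap_voxels: int = 1) -> pd.DataFrame:
    """SG–P-body docking: pairs whose surface-to-surface gap ≤ ``max_gap_voxels``.

    The gap counts the background voxels between the two surfaces: gap 0 ⇒
    the masks overlap or touch, gap 1 (the default) ⇒ at most one background
    voxel separates them, i.e. the bodies touch after one dilation.  Each
    pair is counted once and the relation is symmetric in its arguments.
    Returns one row per event with ``attrs["events_per_sg"]`` = events /
    number of SGs (nan when no SGs).
    """
    sg, pb = sg_labels.labels, pb_labels.labels
    if sg.shape != pb.shape:
        raise ValueError("label maps have different geometries")
    struct = np.ones((3, 3, 3) if sg.shape[0] > 1 else (1, 3, 3), dtype=bool)
    # a gap of g empty voxels means chebyshev set distance g+1, so grow the
    # P-body zone by max_gap+1 and look for overlap with the SG masks
    grow = max_gap_voxels + 1
    pb_zone = ndimage.binary_dilation(pb > 0, structure=struct, iterations=grow)
    pairs: set[tuple[int, int]] = set()
    # grow each P-body's id outward so the contact zone keeps its identity
    _, nearest = ndimage.distance_transform_edt(pb == 0, return_indices=True)
    pb_grown = pb[tuple(nearest)]
    pb_grown[~pb_zone] = 0
    overlap = (sg > 0) & (pb_grown > 0)
    for s, p in zip(sg[overlap].ravel(), pb_grown[overlap].ravel()):
        pairs.add((int(s), int(p)))
    df = pd.DataFrame(sorted(pairs), columns=["sg_label", "pb_label"])
    n_sg = sg_labels.n_objects
    df.attrs["n_events"] = len(df)
    df.attrs["events_per_sg"] = (len(df) / n_sg) if n_sg else np.nan
    return df


def count_and_size(table: pd.DataFrame, n_cells: int | None = None) -> pd.DataFrame:
    """Per-cell object counts and mean physical size from a measurement table.

    ``table`` is a ``measure_objects`` output with a ``cell_id`` column.
    Cells without objects get count 0 when ``n_cells`` is given.
    """
    if len(table) == 0:
        ids = range(1, (n_cells or 0) + 1)
        return pd.DataFrame({"cell_id": list(ids), "count": 0, "mean_size": np.nan})
    g = table.groupby("cell_id")["size"].agg(["count", "mean"])
    g.columns = ["count", "mean_size"]
    g = g.reset_index()
    if n_cells is not None:
        full = pd.DataFrame({"cell_id": np.arange(1, n_cells + 1)})
        g = full.merge(g, on="cell_id", how="left")
        g["count"] = g["count"].fillna(0).astype(int)
    return g
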