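"""Puncta segmentation: Otsu thresholding, connected components, size
filtering, nuclear masks and nuclear-object exclusion.

The pipeline mirrors classic quantitation-module workflows for condensate
imaging: a global Otsu threshold on the channel of interest, full-connectivity
component labelling, removal of sub-resolution components, and — for
cytoplasmic structures — removal of any object that intersects the
DAPI-labelled nuclear regions by as much as a single voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imagestack import ImageStack


class DegenerateHistogramError(ValueError):
    pass


def otsu_threshold(intensities: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximising between-class variance.

    Bins span the observed min–max range.  Between-class variance
    ``w0·w1·(µ0 − µ1)²`` is evaluated at every interior bin edge; on ties the
    lowest maximising edge is returned, so the result is deterministic.
    Voxels with intensity strictly above the returned edge are foreground.

    Raises
    ------
    DegenerateHistogramError
        If the input has fewer than two distinct values.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    if not lo < hi:
        raise DegenerateHistogramError("degenerate histogram: constant image")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)                    # weight of class <= edge k
    m0 = np.cumsum(counts * centers)
    w1 = total - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-np.inf)
    k = int(np.argmax(var_between))           # argmax takes the first (lowest) tie
    return float(edges[k + 1])


@dataclass
class LabelMap:
    """Connected-component labels over one channel, with provenance.

    Labels are consecutive positive integers; 0 is background.
    """

    labels: np.ndarray
    channel: str = ""
    threshold: float = np.nan
    min_size: int = 0
    voxel_size: tuple[float, float, float] | None = None

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def renumbered(self, keep: np.ndarray) -> "LabelMap":
        """Return a copy keeping only the given labels, renumbered 1..n."""
        lut = np.zeros(self.n_objects + 1, dtype=self.labels.dtype)
        lut[np.asarray(sorted(keep), dtype=int)] = np.arange(1, len(keep) + 1)
        return LabelMap(labels=lut[self.labels], channel=self.channel,
                        threshold=self.threshold, min_size=self.min_size,
                        voxel_size=self.voxel_size)


def _structure(ndim_3d: bool = True):
    # full connectivity: 26 in 3D, equivalent to 8 on a single plane
    return np.ones((3, 3, 3), dtype=bool)


def label_objects(channel: np.ndarray, threshold: float,
                  min_size_voxels: int | None = None,
                  connectivity: str = "full",
                  channel_name: str = "",
                  voxel_size: tuple[float, float, float] | None = None) -> LabelMap:
    """Label connected supra-threshold voxels and drop small components.

    ``min_size_voxels`` defaults to 4 for single-plane images and 8 for
    z-stacks.  Connectivity is full (8/26) unless ``connectivity="face"``.
    """
    vol = np.asarray(channel)
    if vol.ndim == 2:
        vol = vol[None]
    is3d = vol.shape[0] > 1
    if min_size_voxels is None:
        min_size_voxels = 8 if is3d else 4
    if connectivity == "full":
        struct = _structure(is3d)
    else:
        struct = ndimage.generate_binary_structure(3, 1)
    mask = vol > threshold
    lab, n = ndimage.label(mask, structure=struct)
    if n:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_size_voxels)
        keep = keep[keep > 0]
        lut = np.zeros(n + 1, dtype=np.int32)
        lut[keep] = np.arange(1, len(keep) + 1)
        lab = lut[lab]
    return LabelMap(labels=lab.astype(np.int32), channel=channel_name,
                    threshold=float(threshold), min_size=int(min_size_voxels),
                    voxel_size=voxel_size)


def segment_nuclei(dapi: np.ndarray, min_nuclear_size_voxels: int = 100) -> np.ndarray:
    """Binary nuclear mask: Otsu on the DAPI channel, holes filled, small
    debris removed.  An empty DAPI channel yields an empty mask with a
    warning rather than an error."""
    vol = np.asarray(dapi)
    if vol.ndim == 2:
        vol = vol[None]
    try:
        thr = otsu_threshold(vol)
    except DegenerateHistogramError:
        warnings.warn("no nucleus found: DAPI channel is constant", stacklevel=2)
        return np.zeros_like(vol, dtype=bool)
    mask = vol > thr
    for z in range(mask.shape[0]):          # fill per-plane so 2D holes close in 3D stacks
        mask[z] = ndimage.binary_fill_holes(mask[z])
    lab, n = ndimage.label(mask, structure=_structure(mask.shape[0] > 1))
    if n == 0:
        warnings.warn("no nucleus found in DAPI channel", stacklevel=2)
        return mask
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= min_nuclear_size_voxels)
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def cell_mask_from_channel(channel: np.ndarray,
                           min_size_voxels: int = 200) -> np.ndarray:
    """Binary cell mask from a cytoplasmic channel: Otsu separates cells from
    the empty field, holes are filled and debris removed."""
    vol = np.asarray(channel)
    if vol.ndim == 2:
        vol = vol[None]
    thr = otsu_threshold(vol)
    mask = vol > thr
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])
    lab, n = ndimage.label(mask, structure=_structure())
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= min_size_voxels)
    return np.isin(lab, keep[keep > 0])


def segment_puncta(stack: ImageStack, channel: str, dapi: str = "dapi",
                   within_cells: bool = True, exclude_nuclear: bool = True,
                   min_size_voxels: int | None = None,
                   cell_mask: np.ndarray | None = None,
                   ) -> tuple[LabelMap, np.ndarray, np.ndarray]:
    """Full puncta-segmentation pipeline for one channel.

    With ``within_cells`` the Otsu threshold for puncta is computed over the
    cell-mask voxels only (puncta vs diffuse cytoplasmic signal) rather than
    over the whole field, where the empty background would dominate the
    histogram.  Returns ``(labels, nuclear_mask, cell_mask)``.
    """
    vol = stack.channel(channel)
    nmask = segment_nuclei(stack.channel(dapi)) if dapi in stack.channel_names \
        else np.zeros_like(np.atleast_3d(vol), dtype=bool)
    if cell_mask is None:
        cell_mask = cell_mask_from_channel(vol) if within_cells else \
            np.ones(vol.shape if vol.ndim == 3 else (1,) + vol.shape, dtype=bool)
    v3 = vol if vol.ndim == 3 else vol[None]
    thr = otsu_threshold(v3[cell_mask]) if within_cells else otsu_threshold(v3)
    labels = label_objects(vol, thr, min_size_voxels=min_size_voxels,
                           channel_name=channel, voxel_size=stack.voxel_size)
    if exclude_nuclear:
        labels = exclude_nuclear_objects(labels, nmask)
    return labels, nmask, cell_mask


def exclude_nuclear_objects(labels: LabelMap, nuclear_mask: np.ndarray) -> LabelMap:
    """Remove every object that intersects the nuclear mask by ≥1 voxel.

    The any-overlap rule removes the object entirely; survivors keep their
    voxel sets and are renumbered consecutively.  Idempotent.
    """
    nm = np.asarray(nuclear_mask, dtype=bool)
    if nm.ndim == 2:
        nm = nm[None]
    if nm.shape != labels.labels.shape:
        raise ValueError("nuclear mask and label map geometries differ")
    n = labels.n_objects
    if n == 0:
        return labels
    touching = np.unique(labels.labels[nm])
    touching = touching[touching > 0]
    keep = np.setdiff1d(np.arange(1, n + 1), touching)
    return labels.renumbered(keep)


def measure_objects(labels: LabelMap, stack: ImageStack,
                    nuclear_mask: np.ndarray | None = None,
                    cell_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Per-object measurements: voxel count, physical size, centroid,
    per-channel mean and integrated intensity, compartment flag and cell
    assignment.

    Physical sizes use the stack's voxel size; when it is missing, sizes are
    reported in voxels and the table carries ``size_unit="voxel"`` plus a
    warning.  Integrated intensity is exactly mean × voxel count.  An object
    is flagged nuclear when any of its voxels lies in ``nuclear_mask``; cell
    assignment takes the nearest nucleus when ``cell_labels`` is absent.
    """
    lab = labels.labels
    n = labels.n_objects
    idx = np.arange(1, n + 1)
    rows: dict[str, np.ndarray | list] = {"label": idx}
    counts = ndimage.sum_labels(np.ones_like(lab), lab, idx) if n else np.array([])
    rows["n_voxels"] = counts.astype(int)
    vs = stack.voxel_size
    if vs is None:
        warnings.warn("voxel size missing: sizes reported in voxels", stacklevel=2)
        rows["size"] = counts.astype(float)
        unit = "voxel"
    else:
        vox = (vs[1] * vs[2]) if lab.shape[0] == 1 else (vs[0] * vs[1] * vs[2])
        rows["size"] = counts * vox
        unit = "um2" if lab.shape[0] == 1 else "um3"
    cents = ndimage.center_of_mass(np.ones_like(lab), lab, idx) if n else []
    cents = np.asarray(cents, dtype=float).reshape(n, 3)
    rows["z"], rows["y"], rows["x"] = cents.T if n else ([], [], [])
    for ci, ch in enumerate(stack.channel_names):
        vol = stack.data[ci]
        mean = ndimage.mean(vol, lab, idx) if n else np.array([])
        rows[f"mean_{ch}"] = mean
        rows[f"integrated_{ch}"] = mean * counts
    if nuclear_mask is not None and n:
        nm = np.asarray(nuclear_mask, dtype=bool)
        if nm.ndim == 2:
            nm = nm[None]
        overlap = ndimage.sum_labels(nm.astype(np.float64), lab, idx)
        rows["nuclear"] = overlap > 0
    if n:
        if cell_labels is not None:
            # majority vote over the object's voxels
            assign = ndimage.labeled_comprehension(
                cell_labels, lab, idx,
                lambda v: np.bincount(v.astype(int)).argmax(), int, 0)
            rows["cell_id"] = assign
    df = pd.DataFrame(rows)
    df.attrs["size_unit"] = unit
    df.attrs["channel"] = labels.channel
    df.attrs["threshold"] = labels.threshold
    return df


def assign_to_nearest_nucleus(object_table: pd.DataFrame,
                              nucleus_centroids: np.ndarray,
                              voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1),
                              ) -> pd.DataFrame:
    """Assign each object to its nearest nucleus (physical distance).

    Used when no membrane marker exists; nucleus ids are 1-based row order.
    """
    out = object_table.copy()
    if len(out) == 0 or len(nucleus_centroids) == 0:
        out["cell_id"] = pd.Series(dtype=int)
        return out
    pts = out[["z", "y", "x"]].to_numpy() * np.asarray(voxel_size)
    nuc = np.asarray(nucleus_centroids, dtype=float) * np.asarray(voxel_size)
    d2 = ((pts[:, None, :] - nuc[None, :, :]) ** 2).sum(axis=2)
    out["cell_id"] = d2.argmin(axis=1) + 1
    return out
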