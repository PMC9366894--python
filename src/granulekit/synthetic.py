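"""Synthetic fluorescence-microscopy scenes, FRAP traces and SG time-lapse
series with exact ground truth.

The generator emulates the statistical structure of fixed- and live-cell
condensate imaging: elliptical nuclei on a DAPI channel, cytoplasm with a
uniform background, punctate condensates (nuclear RNA foci, stress granules,
P-bodies) rendered as PSF-blurred Gaussian spots, SG–P-body "docking"
geometry, two-channel intensity correlation within objects, bleach-recovery
traces that follow a one-phase association exactly, and per-cell SG-count
trajectories with known formation and dispersal times.  Every generator is a
pure function of its spec (a fixed seed reproduces byte-identical output),
and every rendered quantity is recorded in a :class:`GroundTruth` so that
downstream segmentation, colocalisation, docking, FRAP and kinetics code can
be tested for recovery without any external data.

Conventions: arrays are ``(C, Z, Y, X)``; coordinates are 0-based ``z, y, x``
voxels; physical sizes are micrometres with anisotropic voxels defaulting to
``(0.5, 0.1, 0.1)`` µm (500 nm optical sectioning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .imagestack import ImageStack

# FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class GenerationError(ValueError):
    """Raised when a scene spec cannot be realised (names the offending field)."""


# --------------------------------------------------------------------------
# Specs


class CondensateClassSpec(BaseModel):
    """One condensate class (nuclear foci, SGs or P-bodies) in a scene."""

    name: str
    compartment: Literal["nuclear", "cytoplasmic"]
    count_mean: float = Field(ge=0)
    count_dist: Literal["fixed", "poisson"] = "fixed"
    radius_mean_um: float = Field(gt=0, default=0.4)
    radius_sd_um: float = Field(ge=0, default=0.0)
    #: peak (not integrated) intensity added per channel, photons/voxel
    peak_intensity: dict[str, float] = Field(default_factory=dict)
    #: per-channel fraction of objects of this class that carry that channel's
    #: signal at all (content classification fixtures); default all of them
    positive_fraction: dict[str, float] = Field(default_factory=dict)


class NucleusSpec(BaseModel):
    semi_axes_um: tuple[float, float, float] = (2.0, 3.0, 3.0)  # z, y, x
    intensity: float = Field(gt=0, default=300.0)


class NoiseSpec(BaseModel):
    gaussian_sd: float = Field(ge=0, default=0.0)
    poisson: bool = False


class SceneSpec(BaseModel):
    """Full description of one synthetic field of view."""

    image_shape: tuple[int, int, int] = (1, 256, 256)  # z, y, x
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)  # µm, z/y/x
    channels: list[str] = Field(default_factory=lambda: ["dapi", "gfp", "stain"])
    n_cells: int = Field(ge=0, default=3)
    nucleus: NucleusSpec = Field(default_factory=NucleusSpec)
    cytoplasm_scale: float = Field(gt=1.0, default=2.0)
    #: uniform background added over the whole cell ellipsoid, per channel
    cytoplasm_intensity: dict[str, float] = Field(default_factory=lambda: {"gfp": 20.0})
    condensates: list[CondensateClassSpec] = Field(default_factory=list)
    #: fraction of P-bodies placed in contact with an SG
    docking_fraction: float = Field(ge=0, le=1, default=0.0)
    contact_distance_um: float = Field(gt=0, default=0.1)
    #: optional within-object correlation between two channels
    channel_correlation: Optional[float] = Field(default=None, ge=-1, le=1)
    correlated_channels: tuple[str, str] = ("gfp", "stain")
    psf_sigma_um: float = Field(ge=0, default=0.1)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneSpec":
        if "dapi" not in self.channels:
            raise ValueError("channels must include 'dapi' (nuclear stain)")
        cyto = [a * self.cytoplasm_scale for a in self.nucleus.semi_axes_um]
        for c in self.condensates:
            rmax = c.radius_mean_um + 3 * c.radius_sd_um
            if rmax > min(cyto[1], cyto[2]):
                raise ValueError(
                    f"condensates[{c.name!r}].radius_mean_um: radius {rmax:.2f} µm "
                    f"exceeds the cell extent {min(cyto[1:]):.2f} µm"
                )
            for ch in list(c.peak_intensity) + list(c.positive_fraction):
                if ch not in self.channels:
                    raise ValueError(f"condensates[{c.name!r}]: unknown channel {ch!r}")
        return self


# --------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered scene.

    ``objects`` has one row per rendered condensate with its class,
    compartment, cell, centroid (voxels), radius, per-axis Gaussian sigma
    (voxels) and the per-channel integrated intensity actually rendered
    (summed before noise).  ``cell_totals`` holds per-cell per-channel totals
    of the noiseless image over the cell mask.
    """

    objects: pd.DataFrame
    docked_pairs: list[tuple[int, int]]
    nuclei: pd.DataFrame
    cell_labels: np.ndarray
    nuclear_mask: np.ndarray
    noiseless: np.ndarray  # (C, Z, Y, X) pre-noise expectation
    cell_totals: pd.DataFrame
    channels: list[str] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)

    def to_csv(self, path) -> None:
        self.objects.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Rendering helpers


def _spot_sigma_vox(radius_um: float, psf_sigma_um: float,
                    voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for a spot of the given radius.

    The intrinsic spot profile has FWHM equal to the spec radius; the PSF
    adds in quadrature.
    """
    s_um = math.hypot(radius_um / _FWHM, psf_sigma_um)
    return np.array([s_um / v for v in voxel_size])


def _spot_box(shape, center: np.ndarray, sigma: np.ndarray):
    """3σ truncation box of a spot, clipped to the image."""
    nz = shape[0]
    if nz == 1:
        sigma = sigma.copy()
        sigma[0] = 0.0
    lo, hi = [], []
    for ax, n in zip(range(3), shape):
        r = int(math.ceil(3.0 * sigma[ax]))
        lo.append(max(0, int(math.floor(center[ax])) - r))
        hi.append(min(n, int(math.ceil(center[ax])) + r + 1))
    return lo, hi, sigma


def _render_spot(plane: np.ndarray, center: np.ndarray, sigma: np.ndarray,
                 peak: float) -> float:
    """Add a 3σ-truncated Gaussian spot to a (Z, Y, X) array; return its sum."""
    lo, hi, sigma = _spot_box(plane.shape, center, sigma)
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = np.zeros((hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2]))
    for ax, g in enumerate(grids):
        if sigma[ax] > 0:
            q = q + ((g - center[ax]) / sigma[ax]) ** 2
    prof = peak * np.exp(-0.5 * q)
    plane[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += prof
    return float(prof.sum())


def _ellipsoid_mask(shape, center_vox, semi_axes_um, voxel_size) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    q = (((yy - center_vox[1]) * voxel_size[1] / semi_axes_um[1]) ** 2
         + ((xx - center_vox[2]) * voxel_size[2] / semi_axes_um[2]) ** 2)
    if nz > 1:
        q = q + ((zz - center_vox[0]) * voxel_size[0] / semi_axes_um[0]) ** 2
    else:
        q = np.broadcast_to(q, shape).copy()
    return q <= 1.0


# --------------------------------------------------------------------------
# Scene generation


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a scene and return the image plus its exact ground truth.

    Nuclei are uniform ellipsoids on the DAPI channel; each condensate is a
    Gaussian spot truncated at 3σ whose per-channel rendered sum is recorded;
    Poisson shot noise (if enabled) is applied to the expected photon counts
    and Gaussian read noise is added last.
    """
    shape = tuple(spec.image_shape)
    nz, ny, nx = shape
    vsz = tuple(spec.voxel_size)
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_obj, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    img = np.zeros((len(spec.channels),) + shape, dtype=np.float64)
    chan = {c: i for i, c in enumerate(spec.channels)}

    # --- nuclei / cells -----------------------------------------------------
    cyto_ax = tuple(a * spec.cytoplasm_scale for a in spec.nucleus.semi_axes_um)
    centers = []
    ay_v = cyto_ax[1] / vsz[1]
    ax_v = cyto_ax[2] / vsz[2]
    az_v = cyto_ax[0] / vsz[0] if nz > 1 else 0.0
    if spec.n_cells and (2 * ay_v > ny or 2 * ax_v > nx
                         or (nz > 1 and 2 * az_v > nz)):
        raise GenerationError(
            "n_cells/image_shape: a cell of extent "
            f"{tuple(round(2 * a, 1) for a in (az_v, ay_v, ax_v))} voxels "
            f"does not fit in image_shape {shape}"
        )
    # sequential placement can wedge itself (an early cell in the middle of a
    # tight field), so restart the whole configuration on failure
    for _restart in range(100):
        centers = []
        for _ in range(spec.n_cells):
            placed = False
            for _try in range(200):
                cz = rng_place.uniform(az_v, nz - az_v) if nz > 1 else 0.0
                cy = rng_place.uniform(ay_v, ny - ay_v)
                cx = rng_place.uniform(ax_v, nx - ax_v)
                ok = True
                for oz, oy, ox in centers:
                    d = math.sqrt((((cy - oy) * vsz[1]) / (2 * cyto_ax[1])) ** 2
                                  + (((cx - ox) * vsz[2]) / (2 * cyto_ax[2])) ** 2
                                  + ((((cz - oz) * vsz[0]) / (2 * cyto_ax[0])) ** 2
                                     if nz > 1 else 0.0))
                    if d < 1.0:
                        ok = False
                        break
                if ok:
                    centers.append((cz, cy, cx))
                    placed = True
                    break
            if not placed:
                break
        if len(centers) == spec.n_cells:
            break
    else:
        raise GenerationError(
            "n_cells: could not place non-overlapping cells in image_shape "
            f"{shape} after 100 configuration restarts"
        )

    cell_labels = np.zeros(shape, dtype=np.int32)
    nuclear_mask = np.zeros(shape, dtype=bool)
    nuc_rows = []
    for cid, c in enumerate(centers, start=1):
        cmask = _ellipsoid_mask(shape, c, cyto_ax, vsz)
        nmask = _ellipsoid_mask(shape, c, spec.nucleus.semi_axes_um, vsz)
        cell_labels[cmask & (cell_labels == 0)] = cid
        nuclear_mask |= nmask
        img[chan["dapi"]][nmask] += spec.nucleus.intensity
        for ch, level in spec.cytoplasm_intensity.items():
            img[chan[ch]][cmask] += level
        nuc_rows.append({"cell_id": cid, "z": c[0], "y": c[1], "x": c[2],
                         "az_um": spec.nucleus.semi_axes_um[0],
                         "ay_um": spec.nucleus.semi_axes_um[1],
                         "ax_um": spec.nucleus.semi_axes_um[2]})

    # --- condensates --------------------------------------------------------
    obj_rows: list[dict] = []
    docked: list[tuple[int, int]] = []
    sg_by_cell: dict[int, list[int]] = {}
    next_id = 0

    placed: list[tuple[np.ndarray, float]] = []   # (centre voxels, footprint µm)

    def _extent_um(r_um: float) -> float:
        # radius of the rendered footprint: 3σ truncation of spot ⊕ PSF
        return 3.0 * math.hypot(r_um / _FWHM, spec.psf_sigma_um)

    def _dist_um(p, q) -> float:
        d = (np.asarray(p) - np.asarray(q)) * np.array(vsz)
        if nz == 1:
            d[0] = 0.0
        return float(np.linalg.norm(d))

    def _separated(pos, ext, skip: int | None = None) -> bool:
        # footprints of distinct objects stay ≥3 voxels apart, so segmented
        # masks never merge and never dock by accident
        margin = 4.0 * min(vsz[1], vsz[2])
        for j, (q, ext_q) in enumerate(placed):
            if j == skip:
                continue
            if _dist_um(pos, q) < ext + ext_q + margin:
                return False
        return True

    def _sample_position(cid: int, compartment: str, r_um: float) -> np.ndarray:
        c = centers[cid - 1]
        ext = _extent_um(r_um)
        if compartment == "nuclear":
            axes = np.array(spec.nucleus.semi_axes_um)
        else:
            axes = np.array(cyto_ax)
        for _try in range(500):
            u = rng_obj.uniform(-1, 1, size=3)
            if nz == 1:
                u[0] = 0.0
            if np.sum(u ** 2) > 1.0:
                continue
            # keep the whole footprint inside the compartment
            pos_um = u * (axes - ext).clip(min=0.0)
            pos = np.array(c) + pos_um / np.array(vsz)
            if nz == 1:
                pos[0] = 0.0
            if compartment == "cytoplasmic":
                # footprint must clear the nucleus entirely, or the object
                # would be removed by the nuclear-exclusion rule
                grown = tuple(a + ext for a in spec.nucleus.semi_axes_um)
                if _point_in_ellipsoid(pos, c, grown, vsz, nz):
                    continue
            if _separated(pos, ext):
                return pos
        raise GenerationError(
            f"condensates[{compartment}]: placement failed after 500 retries"
        )

    order = [c for c in spec.condensates if c.name != "pbody"] + \
            [c for c in spec.condensates if c.name == "pbody"]
    for cspec in order:
        for cid in range(1, spec.n_cells + 1):
            if cspec.count_dist == "poisson":
                n = int(rng_obj.poisson(cspec.count_mean))
            else:
                n = int(round(cspec.count_mean))
            # exactly round(fraction·n) objects carry each optional channel's
            # signal, so the rendered fraction is the spec fraction
            pos_flags = {}
            for ch, pf in cspec.positive_fraction.items():
                k = int(round(pf * n))
                flags = np.zeros(n, dtype=bool)
                flags[:k] = True
                pos_flags[ch] = rng_obj.permutation(flags)
            for i_obj in range(n):
                r_um = cspec.radius_mean_um
                if cspec.radius_sd_um > 0:
                    r_um = max(0.05, rng_obj.normal(r_um, cspec.radius_sd_um))
                partner = None
                pos = None
                if (cspec.name == "pbody" and spec.docking_fraction > 0
                        and sg_by_cell.get(cid)
                        and rng_obj.uniform() < spec.docking_fraction):
                    # dock against the half-maximum surfaces of the rendered
                    # spots (at radius/2 for a spot whose FWHM is its radius)
                    ext = _extent_um(r_um)
                    for _try in range(200):
                        cand = int(rng_obj.choice(sg_by_cell[cid]))
                        srow = obj_rows[cand]
                        gap = rng_obj.uniform(0.0, spec.contact_distance_um)
                        dist_um = 0.5 * (srow["radius_um"] + r_um) + gap
                        theta = rng_obj.uniform(0, 2 * math.pi)
                        phi = (math.acos(rng_obj.uniform(-1, 1)) if nz > 1
                               else math.pi / 2)
                        d_um = np.array([dist_um * math.cos(phi),
                                         dist_um * math.sin(phi) * math.sin(theta),
                                         dist_um * math.sin(phi) * math.cos(theta)])
                        p = (np.array([srow["z"], srow["y"], srow["x"]])
                             + d_um / np.array(vsz))
                        if nz == 1:
                            p[0] = 0.0
                        c = centers[cid - 1]
                        grown = tuple(a + ext for a in spec.nucleus.semi_axes_um)
                        inner = tuple(max(a - ext, 1e-6) for a in cyto_ax)
                        if _point_in_ellipsoid(p, c, grown, vsz, nz):
                            continue
                        if not _point_in_ellipsoid(p, c, inner, vsz, nz):
                            continue
                        if _separated(p, ext, skip=cand):
                            partner, pos = cand, p
                            break
                if pos is None:
                    partner = None
                    pos = _sample_position(cid, cspec.compartment, r_um)
                placed.append((pos, _extent_um(r_um)))
                sig = _spot_sigma_vox(r_um, spec.psf_sigma_um, vsz)
                row = {"obj_id": next_id, "cell_id": cid, "cls": cspec.name,
                       "compartment": cspec.compartment,
                       "z": pos[0], "y": pos[1], "x": pos[2], "radius_um": r_um,
                       "sigma_z": sig[0], "sigma_y": sig[1], "sigma_x": sig[2]}
                for ch in spec.channels:
                    peak = cspec.peak_intensity.get(ch, 0.0)
                    if ch in pos_flags and not pos_flags[ch][i_obj]:
                        peak = 0.0
                    row[f"peak_{ch}"] = peak
                obj_rows.append(row)
                if cspec.name == "sg":
                    sg_by_cell.setdefault(cid, []).append(next_id)
                if partner is not None:
                    docked.append((partner, next_id))
                next_id += 1

    for row in obj_rows:
        center = np.array([row["z"], row["y"], row["x"]])
        sig = np.array([row["sigma_z"], row["sigma_y"], row["sigma_x"]])
        for ch in spec.channels:
            peak = row[f"peak_{ch}"]
            row[f"intensity_{ch}"] = (
                _render_spot(img[chan[ch]], center, sig, peak) if peak > 0 else 0.0
            )

    noiseless = img.copy()

    # --- noise, applied last ------------------------------------------------
    if spec.noise.poisson:
        img = rng_noise.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.noise.gaussian_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise.gaussian_sd, size=img.shape)

    obj_cols = ["obj_id", "cell_id", "cls", "compartment", "z", "y", "x",
                "radius_um", "sigma_z", "sigma_y", "sigma_x"] + \
               [f"peak_{c}" for c in spec.channels] + \
               [f"intensity_{c}" for c in spec.channels]
    objects = pd.DataFrame(obj_rows, columns=obj_cols)

    tot_rows = []
    for cid in range(1, spec.n_cells + 1):
        m = cell_labels == cid
        for ch in spec.channels:
            tot_rows.append({"cell_id": cid, "channel": ch,
                             "total": float(noiseless[chan[ch]][m].sum())})
    gt = GroundTruth(objects=objects, docked_pairs=docked,
                     nuclei=pd.DataFrame(nuc_rows), cell_labels=cell_labels,
                     nuclear_mask=nuclear_mask, noiseless=noiseless,
                     cell_totals=pd.DataFrame(tot_rows,
                                              columns=["cell_id", "channel", "total"]),
                     channels=list(spec.channels), voxel_size=vsz)
    stack = ImageStack(data=img, channel_names=list(spec.channels), voxel_size=vsz)
    return stack, gt


def _point_in_ellipsoid(p, c, axes_um, vsz, nz) -> bool:
    q = (((p[1] - c[1]) * vsz[1] / axes_um[1]) ** 2
         + ((p[2] - c[2]) * vsz[2] / axes_um[2]) ** 2)
    if nz > 1:
        q += ((p[0] - c[0]) * vsz[0] / axes_um[0]) ** 2
    return q <= 1.0


def ground_truth_labelmap(gt: GroundTruth):
    """Label map built from the generator's own object footprints (the 3σ
    truncation region of every spot), bypassing segmentation.

    Used to evaluate per-object statistics on exactly the voxel sets the
    generator rendered; where footprints would overlap, the first object
    keeps the voxel.
    """
    from .segmentation import LabelMap

    shape = gt.noiseless.shape[1:]
    labels = np.zeros(shape, dtype=np.int32)
    for _, row in gt.objects.iterrows():
        center = np.array([row["z"], row["y"], row["x"]])
        sigma = np.array([row["sigma_z"], row["sigma_y"], row["sigma_x"]])
        lo, hi, _ = _spot_box(shape, center, sigma)
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[sub == 0] = int(row["obj_id"]) + 1
    return LabelMap(labels=labels, channel="ground_truth",
                    voxel_size=gt.voxel_size)


# --------------------------------------------------------------------------
# Correlated two-channel rendering


def generate_correlated_channels(gt: GroundTruth, rho: float,
                                 noise_sd: float = 0.0,
                                 seed: int = 0) -> ImageStack:
    """Build a two-channel stack whose within-object Pearson correlation is rho.

    Channel A re-renders every ground-truth object noise-free (using its
    recorded first-channel peak, or unit peak when absent).  Within each
    object's 3σ footprint, channel B is the exact rho-mixture
    ``B = µ + σ·(rho·z_A + sqrt(1−rho²)·ε)`` of the standardised channel-A
    profile ``z_A`` and independent standard-normal noise ε, so the expected
    within-object Pearson coefficient equals ``rho``.  ``noise_sd`` adds
    whole-image Gaussian measurement noise afterwards.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    shape = gt.noiseless.shape[1:]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cha = np.zeros(shape, dtype=np.float64)
    chb = np.zeros(shape, dtype=np.float64)
    peak_col = next((f"peak_{c}" for c in gt.channels
                     if f"peak_{c}" in gt.objects and gt.objects[f"peak_{c}"].max() > 0),
                    None)
    for _, row in gt.objects.iterrows():
        center = np.array([row["z"], row["y"], row["x"]])
        sig = np.array([row["sigma_z"], row["sigma_y"], row["sigma_x"]])
        peak = float(row[peak_col]) if peak_col else 100.0
        if peak <= 0:
            peak = 100.0
        sub = np.zeros(shape, dtype=np.float64)
        _render_spot(sub, center, sig, peak)
        idx = sub > 0
        a = sub[idx]
        mu, sd = a.mean(), a.std()
        if sd == 0:
            b = a.copy()
        else:
            z = (a - mu) / sd
            eps = rng.standard_normal(a.size)
            b = mu + sd * (rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * eps)
        cha[idx] += a
        chb[idx] += b
    if noise_sd > 0:
        cha = cha + rng.normal(0.0, noise_sd, size=shape)
        chb = chb + rng.normal(0.0, noise_sd, size=shape)
    data = np.stack([cha, chb])
    return ImageStack(data=data, channel_names=["chA", "chB"],
                      voxel_size=gt.voxel_size)


# --------------------------------------------------------------------------
# FRAP simulation


class FRAPSimSpec(BaseModel):
    """Generator settings for one bleach-recovery trace.

    The normalised recovery of the simulated trace is exactly a one-phase
    association with plateau ``mobile_fraction_true`` and half-time
    ``t_half_true``; acquisition photobleaching multiplies the whole signal
    by ``(1 − acquisition_bleach_rate)`` per frame and affects the reference
    ROI identically.  ``noise_sd`` is the Gaussian measurement noise as a
    fraction of the bleached amplitude, i.e. of the span that normalisation
    maps to 0–100 % (0.03 ⇒ ~3 percentage points on the normalised trace).
    """

    mobile_fraction_true: float = Field(ge=0, le=100, default=70.0)
    t_half_true: float = Field(gt=0, default=2.0)
    bleach_depth: float = Field(gt=0, le=1, default=0.5)
    n_pre: int = Field(ge=1, default=3)
    n_post: int = Field(ge=2, default=25)
    timestamps: Optional[list[float]] = None
    acquisition_bleach_rate: float = Field(ge=0, lt=1, default=0.0)
    background_level: float = Field(ge=0, default=50.0)
    pre_bleach_level: float = Field(gt=0, default=1000.0)
    noise_sd: float = Field(ge=0, default=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FRAPSimSpec":
        if self.timestamps is not None:
            t = np.asarray(self.timestamps)
            if len(t) != self.n_pre + self.n_post:
                raise ValueError("timestamps length must equal n_pre + n_post")
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        return self


def default_frap_timestamps(n_pre: int = 3, n_post: int = 25) -> np.ndarray:
    """Adaptive sampling: 1 s pre-bleach frames, post intervals growing
    geometrically from 0.2 s towards 5 s (dense early, sparse late)."""
    pre = -np.arange(n_pre, 0, -1, dtype=float)
    dt, post, t = 0.1, [0.0], 0.0
    for _ in range(n_post - 1):
        t += dt
        post.append(t)
        dt = min(dt * 1.35, 5.0)
    return np.concatenate([pre, np.asarray(post)])


def simulate_frap_trace(spec: FRAPSimSpec):
    """Simulate one FRAP trace; ground-truth Fm and t½ ride in ``trace.truth``."""
    from .frap import FRAPTrace

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.timestamps is not None:
        t = np.asarray(spec.timestamps, dtype=float)
    else:
        t = default_frap_timestamps(spec.n_pre, spec.n_post)
    n = len(t)
    k = np.arange(n)
    decay = (1.0 - spec.acquisition_bleach_rate) ** k

    S = np.empty(n)
    S[:spec.n_pre] = spec.pre_bleach_level
    tpost = t[spec.n_pre:] - t[spec.n_pre]
    d, fm = spec.bleach_depth, spec.mobile_fraction_true / 100.0
    S[spec.n_pre:] = spec.pre_bleach_level * (
        (1 - d) + d * fm * (1.0 - np.exp2(-tpost / spec.t_half_true))
    )
    sd = spec.noise_sd * spec.bleach_depth * spec.pre_bleach_level
    roi = spec.background_level + decay * S
    ref = spec.background_level + decay * spec.pre_bleach_level
    if sd > 0:
        roi = roi + rng.normal(0, sd, n)
        ref = ref + rng.normal(0, sd, n)
    bg = np.full(n, spec.background_level)
    if sd > 0:
        bg = bg + rng.normal(0, 0.1 * sd, n)
    return FRAPTrace(
        time_s=t, roi=roi, background=bg, reference=ref,
        first_post_index=spec.n_pre,
        truth={"mobile_fraction": spec.mobile_fraction_true,
               "t_half": spec.t_half_true},
    )


# --------------------------------------------------------------------------
# Time-lapse SG-count simulation


class KineticsSimSpec(BaseModel):
    """Per-cohort SG-count trajectory model.

    Counts are zero before a per-cell formation onset, rise monotonically
    (cumulative Poisson arrivals) to a per-cell plateau, and — when a
    dispersal phase is configured — fall monotonically to zero after a
    per-cell dispersal onset.
    """

    n_cells: int = Field(ge=1, default=25)
    frame_interval_min: float = Field(ge=3.0, default=3.0)
    t_end_min: float = Field(gt=0, default=120.0)
    onset_mean_min: float = Field(ge=0, default=24.0)
    onset_sd_min: float = Field(ge=0, default=8.0)
    rise_rate_per_min: float = Field(gt=0, default=1.0)
    plateau_mean: float = Field(gt=0, default=12.0)
    dispersal_onset_mean_min: Optional[float] = None
    dispersal_onset_sd_min: float = Field(ge=0, default=10.0)
    decay_rate_per_min: float = Field(gt=0, default=0.5)
    start_with_sgs: bool = False
    condition: str = "control"
    seed: int = 0


def simulate_timelapse_counts(spec: KineticsSimSpec):
    """Simulate per-cell SG-count trajectories plus their kinetic truth.

    Returns ``(series_list, truth)`` where truth records each cell's true
    formation time (first frame with ≥5 SGs, NaN when censored) and true
    dispersal time (first return to 0 after SGs were present, NaN when
    censored).
    """
    from .kinetics import TimeLapseSeries

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    times = np.arange(0.0, spec.t_end_min + 1e-9, spec.frame_interval_min)
    series, truth_rows = [], []
    for cid in range(spec.n_cells):
        plateau = max(1, int(rng.poisson(spec.plateau_mean)))
        counts = np.zeros(len(times), dtype=int)
        if spec.start_with_sgs:
            counts[:] = plateau
        else:
            onset = max(0.0, rng.normal(spec.onset_mean_min, spec.onset_sd_min))
            acc = 0
            for i, t in enumerate(times):
                if t >= onset and acc < plateau:
                    lam = spec.rise_rate_per_min * spec.frame_interval_min
                    acc = min(plateau, acc + int(rng.poisson(lam)))
                counts[i] = acc
        if spec.dispersal_onset_mean_min is not None:
            d_onset = max(0.0, rng.normal(spec.dispersal_onset_mean_min,
                                          spec.dispersal_onset_sd_min))
            rem = 0
            for i, t in enumerate(times):
                if t >= d_onset:
                    lam = spec.decay_rate_per_min * spec.frame_interval_min
                    rem = rem + int(rng.poisson(lam))
                counts[i] = max(0, counts[i] - rem)
        s = TimeLapseSeries(cell_id=f"{spec.condition}_{cid}", time_min=times,
                            sg_count=counts, condition=spec.condition)
        series.append(s)
        formed = np.flatnonzero(counts >= 5)
        zero_after = np.flatnonzero((counts == 0)
                                    & (np.maximum.accumulate(counts) > 0))
        truth_rows.append({
            "cell_id": s.cell_id,
            "formation_time": float(times[formed[0]]) if formed.size else np.nan,
            "formation_censored": formed.size == 0,
            "dispersal_time": float(times[zero_after[0]]) if zero_after.size else np.nan,
            "dispersal_censored": zero_after.size == 0,
        })
    return series, pd.DataFrame(truth_rows)
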