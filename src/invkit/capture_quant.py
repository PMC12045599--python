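"""Per-cell fluorescence measurements and relocalization ratios.

Turns registered multi-channel images of vesicle-capture experiments into the
mask-arithmetic metrics used to quantify relocalization and co-relocation:

* the mitochondrial mask (segmented from the MitoTrap channel) and a
  "cytoplasm" ring mask (the mito mask dilated eight times with the mito mask
  excluded),
* background-subtracted summed fluorescence in each region
  (``F_mito``, ``F_cyto``, ``F_total = F_mito + F_cyto``),
* per-cell ratios: ``F_mito/F_total`` for fixed-cell experiments,
  ``F_post/F_pre`` (mito region) for live experiments, and the cytoplasmic
  fraction ``F_cyto/F_total`` whose relative decrease under capture reports
  the relocalizable vesicle pool size.

Cells with ``F_mito/F_cyto < 1`` in the FKBP channel post-treatment are
flagged as non-responders (capture failed) and excluded from summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters
from skimage.morphology import remove_small_objects
from skimage.registration import phase_cross_correlation

from invkit.errors import ConfigurationError

__all__ = [
    "FieldImage",
    "MaskSet",
    "CellMeasurement",
    "RelocalizationRecord",
    "LossResult",
    "register_channels",
    "segment_mitochondria",
    "make_cytoplasm_mask",
    "label_cells",
    "build_masks",
    "estimate_background",
    "measure_cell",
    "measure_field",
    "compute_ratios",
    "cytoplasmic_loss",
]

_STRUCT = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FieldImage:
    """A multi-channel field with channel-role metadata.

    ``data`` has axes (C, Y, X) or (T, C, Y, X).  ``roles`` maps role names
    (``fkbp_marker``, ``poi``, ``mitotrap``) to channel indices.
    """

    data: np.ndarray
    roles: dict[str, int]
    pixel_size: float = 1.0          # um / pixel
    frame_interval: float = 1.0      # s
    onset_frame: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ConfigurationError("FieldImage data must be (C,Y,X) or (T,C,Y,X)")
        n_channels = self.data.shape[-3]
        for role, idx in self.roles.items():
            if not 0 <= idx < n_channels:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {idx}, image has {n_channels}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.data.ndim == 4 else 1

    def channel(self, role: str, frame: int | None = None) -> np.ndarray:
        idx = self.roles[role]
        if self.data.ndim == 3:
            return self.data[idx]
        return self.data[frame if frame is not None else 0, idx]


@dataclass
class MaskSet:
    """Disjoint mitochondrial / cytoplasmic-ring masks and the cell label map."""

    mito_mask: np.ndarray
    cyto_mask: np.ndarray
    cell_label_map: np.ndarray

    def __post_init__(self) -> None:
        if (self.mito_mask & self.cyto_mask).any():
            raise ConfigurationError("mito_mask and cyto_mask must be disjoint")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_label_map)
        return ids[ids > 0]


@dataclass
class CellMeasurement:
    """Background-subtracted summed fluorescence of one cell, one channel."""

    cell_id: int
    channel: str
    f_mito: float
    f_cyto: float
    replicate: str | int = 0
    condition: str = ""
    frame: int | None = None

    @property
    def f_total(self) -> float:
        return self.f_mito + self.f_cyto


@dataclass
class RelocalizationRecord:
    """Per-cell relocalization ratios derived from :class:`CellMeasurement`."""

    cell_id: int
    channel: str
    ratio_fixed: float | None = None     # F_mito / F_total
    ratio_live: float | None = None      # F_mito(post) / F_mito(pre)
    cyto_fraction: float | None = None   # F_cyto / F_total
    responder: bool = True
    replicate: str | int = 0
    condition: str = ""


@dataclass
class LossResult:
    """Percent decrease of the cytoplasmic fraction, per replicate and overall."""

    per_replicate: pd.Series
    grand_mean: float
    pooled: float
    flagged_negative: bool = False


# ---------------------------------------------------------------------------
# registration & segmentation
# ---------------------------------------------------------------------------

def register_channels(
    images: np.ndarray,
    reference_channel: int = 0,
    upsample_factor: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-register channels onto a reference by cross-correlation.

    Returns the shifted stack and the per-channel (dy, dx) displacement of
    each channel relative to the reference (the inverse shift is applied to
    align it).  Flat (zero-variance) channels produce a zero shift with a
    warning.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ConfigurationError("need a (C, Y, X) stack with >= 2 channels")
    ref = images[reference_channel]
    out = images.copy()
    shifts = np.zeros((images.shape[0], 2))
    for c in range(images.shape[0]):
        if c == reference_channel:
            continue
        if np.ptp(images[c]) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"channel {c}: flat image, assuming zero shift")
            continue
        corr, _, _ = phase_cross_correlation(ref, images[c],
                                             upsample_factor=upsample_factor)
        shifts[c] = -corr     # displacement of the channel relative to the reference
        out[c] = ndimage.shift(images[c], corr, order=1, mode="nearest")
    return out, shifts


def segment_mitochondria(
    image: np.ndarray,
    sigma: float = 1.0,
    min_area: int = 10,
    threshold: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Segment the mitochondrial network from a MitoTrap channel.

    Gaussian smoothing followed by an automatic (Otsu) threshold; objects
    smaller than ``min_area`` pixels are removed.  An empty or flat image
    yields an empty mask with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigurationError("segment_mitochondria expects a 2D image")
    if invert:
        image = image.max() - image
    smooth = ndimage.gaussian_filter(image, sigma)
    if np.ptp(smooth) == 0:
        warnings.warn("flat image: returning an empty mitochondrial mask")
        return np.zeros(image.shape, dtype=bool)
    thr = threshold if threshold is not None else filters.threshold_otsu(smooth)
    mask = smooth > thr
    return remove_small_objects(mask, max_size=min_area - 1)


def make_cytoplasm_mask(mito_mask: np.ndarray, n_dilations: int = 8) -> np.ndarray:
    """Dilate the mito mask ``n_dilations`` times (3x3 square) and exclude it.

    A single-pixel mask with the default eight dilations yields a 17x17 square
    minus its centre: 288 cytoplasm pixels.
    """
    if n_dilations < 1:
        raise ConfigurationError("n_dilations must be >= 1")
    mito_mask = np.asarray(mito_mask, dtype=bool)
    if not mito_mask.any():
        return np.zeros_like(mito_mask)
    dilated = ndimage.binary_dilation(mito_mask, structure=_STRUCT,
                                      iterations=n_dilations)
    return dilated & ~mito_mask


def label_cells(mito_mask: np.ndarray, n_dilations: int = 8) -> np.ndarray:
    """Label cells as connected components of the dilated mitochondrial mask."""
    footprint = ndimage.binary_dilation(np.asarray(mito_mask, bool),
                                        structure=_STRUCT, iterations=n_dilations)
    labels, _ = ndimage.label(footprint, structure=_STRUCT)
    return labels


def build_masks(mitotrap_channel: np.ndarray, n_dilations: int = 8,
                **segment_kwargs) -> MaskSet:
    """Segment mitochondria and derive the full :class:`MaskSet` for a field."""
    mito = segment_mitochondria(mitotrap_channel, **segment_kwargs)
    cyto = make_cytoplasm_mask(mito, n_dilations) if mito.any() \
        else np.zeros_like(mito)
    cells = label_cells(mito, n_dilations) if mito.any() \
        else np.zeros(mito.shape, dtype=np.int32)
    return MaskSet(mito, cyto, cells)


def estimate_background(image: np.ndarray, masks: MaskSet,
                        pad: int = 4) -> float:
    """Median intensity outside the (padded) union of all cell footprints."""
    outside = ~ndimage.binary_dilation(masks.cell_label_map > 0,
                                       structure=_STRUCT, iterations=pad)
    if not outside.any():
        warnings.warn("no background pixels outside cell masks; using image min")
        return float(np.min(image))
    return float(np.median(image[outside]))


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _region_sum(image: np.ndarray, region: np.ndarray, background: float) -> float:
    """Sum of (pixel - background) over the region, negative terms clipped."""
    if not region.any():
        return 0.0
    return float(np.clip(image[region] - background, 0.0, None).sum())


def measure_cell(
    image: np.ndarray,
    masks: MaskSet,
    cell_id: int,
    background: float = 0.0,
    channel: str = "",
    **meta,
) -> CellMeasurement:
    """Measure one channel image for one cell.

    ``F_region = sum(max(pixel - background, 0))`` over the cell's mito and
    cyto regions.  An empty region contributes 0 with a warning.
    """
    if background < 0:
        raise ConfigurationError("background must be >= 0")
    in_cell = masks.cell_label_map == cell_id
    mito = masks.mito_mask & in_cell
    cyto = masks.cyto_mask & in_cell
    if not mito.any() or not cyto.any():
        warnings.warn(f"cell {cell_id}: empty mito or cyto region")
    return CellMeasurement(cell_id=cell_id, channel=channel,
                           f_mito=_region_sum(image, mito, background),
                           f_cyto=_region_sum(image, cyto, background),
                           **meta)


def measure_field(
    field_image: FieldImage,
    masks: MaskSet,
    background: dict[str, float] | None = None,
    roles: tuple[str, ...] = ("fkbp_marker", "poi"),
    frames: list[int] | None = None,
    replicate: str | int = 0,
    condition: str = "",
) -> pd.DataFrame:
    """Measure every cell and requested channel role of a field.

    Returns a tidy DataFrame with columns ``cell_id, channel, frame,
    replicate, condition, F_mito, F_cyto, F_total``.  ``background`` maps
    role -> intensity; if omitted it is estimated per channel from pixels
    outside the cell footprints.
    """
    rows = []
    frame_list = frames if frames is not None else (
        list(range(field_image.n_frames)) if field_image.data.ndim == 4 else [None])
    for role in roles:
        for fr in frame_list:
            img = field_image.channel(role, fr)
            bg = (background or {}).get(role)
            if bg is None:
                bg = estimate_background(img, masks)
            for cid in masks.cell_ids:
                m = measure_cell(img, masks, int(cid), bg, channel=role)
                rows.append({"cell_id": int(cid), "channel": role, "frame": fr,
                             "replicate": replicate, "condition": condition,
                             "F_mito": m.f_mito, "F_cyto": m.f_cyto,
                             "F_total": m.f_total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ratios and losses
# ---------------------------------------------------------------------------

def compute_ratios(
    cells: pd.DataFrame,
    mode: str = "fixed",
    fkbp_channel: str = "fkbp_marker",
    apply_responder_filter: bool = True,
    pre_frame: int | None = None,
    post_frame: int | None = None,
) -> pd.DataFrame:
    """Derive relocalization records from per-cell measurements.

    Parameters
    ----------
    cells : output of :func:`measure_field` (fixed mode: one frame per cell;
        live mode: a ``frame`` column with pre and post timepoints).
    mode : ``"fixed"`` (``F_mito/F_total`` at a single timepoint) or
        ``"live"`` (``F_post/F_pre`` in the mito region).
    apply_responder_filter : flag cells with ``F_mito/F_cyto < 1`` in the
        FKBP channel (post-treatment) as non-responders.  Disable for
        untreated control measurements, where the rule does not apply.

    Cells with ``F_total = 0`` (fixed) or ``F_pre = 0`` (live) are dropped
    with a warning.  Returns one row per cell x channel with ``ratio_fixed``,
    ``ratio_live``, ``cyto_fraction`` and ``responder`` columns.
    """
    if mode not in ("fixed", "live"):
        raise ConfigurationError("mode must be 'fixed' or 'live'")
    cells = cells.copy()
    if mode == "live":
        frames = sorted(f for f in cells["frame"].dropna().unique())
        if len(frames) < 2:
            raise ConfigurationError("live mode needs pre and post timepoints")
        pre = pre_frame if pre_frame is not None else frames[0]
        post = post_frame if post_frame is not None else frames[-1]
        pre_df = cells[cells["frame"] == pre].set_index(["cell_id", "channel"])
        post_df = cells[cells["frame"] == post].set_index(["cell_id", "channel"])
        merged = post_df.join(pre_df, lsuffix="_post", rsuffix="_pre")
        bad = merged["F_mito_pre"] <= 0
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} records with F_pre = 0")
            merged = merged[~bad]
        out = merged.reset_index()
        out["ratio_live"] = out["F_mito_post"] / out["F_mito_pre"]
        out["ratio_fixed"] = np.nan
        tot = out["F_total_post"]
        out["cyto_fraction"] = np.where(tot > 0, out["F_cyto_post"] / tot, np.nan)
        resp_src = out.rename(columns={"F_mito_post": "F_mito",
                                       "F_cyto_post": "F_cyto"})
        out["replicate"] = out.get("replicate_post", 0)
        out["condition"] = out.get("condition_post", "")
    else:
        bad = cells["F_total"] <= 0
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} records with F_total = 0")
            cells = cells[~bad]
        out = cells.copy()
        out["ratio_fixed"] = out["F_mito"] / out["F_total"]
        out["ratio_live"] = np.nan
        out["cyto_fraction"] = out["F_cyto"] / out["F_total"]
        resp_src = out

    if apply_responder_filter:
        fk = resp_src[resp_src["channel"] == fkbp_channel]
        # strict "< 1": ratios equal to 1 are kept
        nonresp = set(fk.loc[fk["F_mito"] / fk["F_cyto"] < 1.0, "cell_id"])
    else:
        nonresp = set()
    out["responder"] = ~out["cell_id"].isin(nonresp)
    keep = ["cell_id", "channel", "ratio_fixed", "ratio_live", "cyto_fraction",
            "responder", "replicate", "condition"]
    return out[[c for c in keep if c in out.columns]].reset_index(drop=True)


def cytoplasmic_loss(
    treated: pd.DataFrame,
    reference: pd.DataFrame,
    channel: str | None = None,
) -> LossResult:
    """Percent decrease of the mean cytoplasmic fraction under treatment.

    ``loss% = 100 * (mean cf(reference) - mean cf(treated)) / mean cf(reference)``
    computed per replicate (replicates paired by label) and as a grand mean
    over replicates; ``pooled`` ignores replicate structure.  Only responder
    records are used.  A negative value (treated > reference) is reported and
    flagged.
    """
    def _prep(df: pd.DataFrame) -> pd.DataFrame:
        df = df[df["responder"]]
        if channel is not None:
            df = df[df["channel"] == channel]
        return df.dropna(subset=["cyto_fraction"])

    treated, reference = _prep(treated), _prep(reference)
    if treated.empty or reference.empty:
        raise ConfigurationError("treated and reference lists must be non-empty")
    ref_mean = reference["cyto_fraction"].mean()
    if ref_mean == 0:
        raise ConfigurationError("reference mean cytoplasmic fraction is zero")
    pooled = 100.0 * (ref_mean - treated["cyto_fraction"].mean()) / ref_mean
    t_rep = treated.groupby("replicate")["cyto_fraction"].mean()
    r_rep = reference.groupby("replicate")["cyto_fraction"].mean()
    common = t_rep.index.intersection(r_rep.index)
    if len(common):
        per_rep = 100.0 * (r_rep[common] - t_rep[common]) / r_rep[common]
    else:  # unpaired replicates: compare each treated replicate to the grand reference
        per_rep = 100.0 * (ref_mean - t_rep) / ref_mean
    grand = float(per_rep.mean())
    flagged = grand < 0
    if flagged:
        warnings.warn("treated cytoplasmic fraction exceeds reference "
                      "(negative loss)")
    return LossResult(per_replicate=per_rep, grand_mean=grand,
                      pooled=float(pooled), flagged_negative=flagged)
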