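"""Synthetic microscopy and proteomics data with known ground truth.

The generators in this module emulate the statistical structure of the
experiments the rest of the package quantifies:

* **Vesicle capture ("knocksideways") fields** — cells with a mitochondrial
  network, two diffuse vesicle-marker channels (an INV marker, channel A, and
  an ATG9A-like marker, channel B) and a MitoTrap channel.  A configurable
  fraction of each marker rides on sub-resolution vesicles; adding rapalog
  moves every vesicle carrying the FKBP-tagged marker onto the mitochondrial
  network, either instantaneously (fixed pre/post pairs) or with first-order
  kinetics of time constant ``tau_capture`` (time lapses).
* **3D puncta stacks** — autophagosome-like blobs of known physical volume in
  an anisotropic z-stack.
* **LFQ protein-group tables** — label-free quantification intensities with a
  spiked enriched set, replicate structure, left-censored (intensity
  dependent) missingness and annotation priors.

Every generator returns a ground-truth object carrying the exact bookkeeping
(per-vesicle coordinates and channel membership, per-blob voxel volumes, the
spiked protein set) that recovery tests assert against.

Signal bookkeeping
------------------
Vesicle markers are split into a vesicle-bound (relocalizable) pool and a
diffuse pool.  ``pool_fraction`` is the relocalizable fraction of the marker's
*cytoplasmic* signal, where "cytoplasmic" means outside the mitochondrial
footprint; the diffuse pool overlays the whole cell (cytosol lies above and
below mitochondria in projection).  With mitochondria occupying an area
fraction ``m`` of the cell footprint, the vesicle-bound fraction of the total
signal is ``V = p(1-m)/(1-pm)``, which makes the relative cytoplasmic loss on
complete capture equal ``p`` exactly in the noise-free limit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from invkit.errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "LfqSimConfig",
    "GroundTruth",
    "PunctaGroundTruth",
    "LfqGroundTruth",
    "simulate_fixed_capture_pair",
    "simulate_capture_timelapse",
    "simulate_puncta_stack",
    "simulate_lfq_experiment",
    "simulate_trace",
]

#: channel order used for all simulated capture fields
CHANNELS = ("A", "B", "mitotrap")
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated vesicle-capture experiment.

    Defaults encode the study conditions of the INV / ATG9A-vesicle capture
    experiments: the INV marker (channel A) has a relocalizable pool of 71.5%
    of its cytoplasmic signal, the ATG9A-like marker (channel B) one of 41%,
    every B vesicle also carries the A marker (``overlap_fraction = 1``) and
    the A:B vesicle count ratio of 148:30 puts 20.3% of A's vesicle-bound
    signal on dual vesicles.
    """

    image_shape: tuple[int, int] = (480, 480)
    n_cells: int = 9
    pixel_size: float = 0.065        # um / pixel
    frame_interval: float = 2.0      # s
    n_frames: int = 60
    onset_frame: int = 10            # frame index of rapalog addition
    mito_density: float = 0.30       # mito area as fraction of the cell footprint
    vesicles_per_channel: tuple[int, int] = (148, 30)
    pool_fraction_A: float = 0.715
    pool_fraction_B: float = 0.41
    overlap_fraction: float = 1.0    # fraction of B vesicles also carrying A
    tau_capture: float = 20.0        # s
    background_level: float = 50.0
    noise_sd: float = 2.0            # gaussian read noise, intensity units
    photon_scale: float = 0.5        # Poisson scaling; 0 disables shot noise
    signal_per_cell: float = 2.0e5   # summed marker signal per cell, per channel
    mito_intensity: float = 300.0    # MitoTrap channel amplitude above background
    fkbp_channel: str = "A"          # which marker is FKBP-tagged (captured)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pool_fraction_A", "pool_fraction_B", "overlap_fraction",
                     "mito_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must be in [0, 1]")
        if self.tau_capture <= 0:
            raise ConfigurationError("tau_capture must be > 0")
        if not 0 <= self.onset_frame < self.n_frames:
            raise ConfigurationError("onset_frame must be < n_frames")
        if self.fkbp_channel not in ("A", "B"):
            raise ConfigurationError("fkbp_channel must be 'A' or 'B'")
        if len(self.image_shape) != 2 or min(self.image_shape) < 96:
            raise ConfigurationError("image_shape must be 2D and >= 96 px per axis")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        n_a, n_b = self.vesicles_per_channel
        dual = round(self.overlap_fraction * n_b)
        if dual > n_a:
            raise ConfigurationError(
                "overlap_fraction * n_B vesicles exceed the channel-A vesicle count"
            )
        if self.noise_sd < 0 or self.photon_scale < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class LfqSimConfig:
    """Parameters of a simulated label-free quantification experiment.

    The replicate structure follows the pulldown experiments being emulated:
    two independent runs of three replicates each, i.e. six replicates per
    condition.  ``log2_effect_mean`` defaults to three within-condition
    standard deviations (3 x 0.6 log2 units); at this effect size both the
    fold-change gate (FC > 2) and the significance gate are comfortably
    passable with six replicates.
    """

    n_proteins: int = 2000
    n_replicates: int = 6
    n_enriched: int = 50
    log2_effect_mean: float = 1.8
    log2_effect_sd: float = 0.2
    base_mean: float = 25.0          # log2 intensity
    base_sd: float = 2.0
    replicate_sd: float = 0.6        # within-condition log2 sd
    dropout_midpoint: float | None = 20.0   # log2 intensity of 50% dropout; None = off
    dropout_steepness: float = 0.8
    secreted_prob: float = 0.072
    secreted_prob_enriched: float = 0.105
    tmd_prob: float = 0.17
    tmd_prob_enriched: float = 0.28
    tmd_mean_extra: float = 1.5      # extra TMDs (Poisson) for TMD-containing proteins
    reference_sets: tuple[tuple[str, float, float], ...] = (
        ("atg9_vesicle", 0.107, 0.238),
    )
    n_contaminants: int = 5
    condition_a: str = "pulldown"
    condition_b: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ConfigurationError("n_enriched must be <= n_proteins")
        for name in ("secreted_prob", "secreted_prob_enriched",
                     "tmd_prob", "tmd_prob_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must be in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")

    def replace(self, **kwargs) -> "LfqSimConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact bookkeeping of a simulated capture field.

    Attributes
    ----------
    cell_labels : 2D int array, 0 = background, 1..n_cells = cell footprints.
    mito_mask : 2D bool array of the true mitochondrial network.
    vesicles : DataFrame with one row per vesicle: ``cell``, original position
        ``(y, x)``, capture position ``(y_cap, x_cap)``, channel membership
        ``carries_A``/``carries_B``, per-channel amplitudes, ``relocalizable``
        (w.r.t. the FKBP-tagged channel) and ``capture_time`` in seconds
        (``inf`` for vesicles that never move).
    cells : DataFrame with per-cell areas and signal bookkeeping
        (vesicle-bound fraction ``v_X`` and diffuse-over-mito fraction
        ``g_X`` per channel).
    """

    config: SimulationConfig
    cell_labels: np.ndarray
    mito_mask: np.ndarray
    vesicles: pd.DataFrame
    cells: pd.DataFrame

    @property
    def tau_capture(self) -> float:
        return self.config.tau_capture

    @property
    def subset_share(self) -> float:
        """Relocalizable-by-B channel-A signal over all relocalizable A signal.

        Recomputed from the vesicle lists, not from the configuration.
        """
        ves = self.vesicles
        a_total = ves.loc[ves.carries_A, "amp_A"].sum()
        a_dual = ves.loc[ves.carries_A & ves.carries_B, "amp_A"].sum()
        return float(a_dual / a_total) if a_total > 0 else float("nan")

    def expected_direct_loss(self, channel: str) -> float:
        """Expected % cytoplasmic loss of ``channel`` on its own full capture."""
        return 100.0 * getattr(self.config, f"pool_fraction_{channel}")

    def expected_co_loss(self, channel: str = "A") -> float:
        """Expected % cytoplasmic loss of ``channel`` when the *other* marker
        is captured (only dual vesicles move).  Recomputed from vesicle lists."""
        other = "B" if channel == "A" else "A"
        ves = self.vesicles
        amp = ves[f"amp_{channel}"]
        dual_frac = amp[ves[f"carries_{other}"]].sum() / amp.sum()
        pool = getattr(self.config, f"pool_fraction_{channel}")
        return 100.0 * pool * float(dual_frac)

    def total_signal(self, image: np.ndarray, channel: str) -> float:
        """Summed background-free signal of a channel inside cell footprints."""
        c = CHANNEL_INDEX[channel]
        img = image[c] if image.ndim == 3 else image
        return float((img - self.config.background_level)[self.cell_labels > 0].sum())


@dataclass
class PunctaGroundTruth:
    """Per-blob bookkeeping of a simulated puncta stack."""

    labels: np.ndarray               # 3D int label stack on the generated grid
    volumes_um3: np.ndarray          # voxel-count volume per blob, um^3
    requested_um3: np.ndarray
    centers: np.ndarray              # (n, 3) physical-coordinate blob centres (z, y, x um)
    voxel_size: tuple[float, float, float]   # (z, y, x) um

    @property
    def n_puncta(self) -> int:
        return len(self.volumes_um3)


@dataclass
class LfqGroundTruth:
    """Spiked set and true effects of a simulated LFQ experiment."""

    config: LfqSimConfig
    enriched: list[str]
    effects: pd.Series               # true log2 effect per protein (0 for nulls)
    annotations: pd.DataFrame


# ---------------------------------------------------------------------------
# capture-field construction
# ---------------------------------------------------------------------------

_SPOT_SIGMA = 1.0                    # px; sub-resolution vesicles are diffraction limited
_N_DILATIONS = 8                     # ring width used to define the cell footprint
_TILE_MARGIN = 14                    # keeps dilated masks and spot kernels inside tiles
_STRUCT = np.ones((3, 3), dtype=bool)


def _spot_kernel(sigma: float = _SPOT_SIGMA, radius: int = 4) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


_KERNEL = _spot_kernel()
_KRAD = _KERNEL.shape[0] // 2


def _add_spot(img: np.ndarray, y: int, x: int, amp: float) -> None:
    """Add an ``amp``-normalised Gaussian spot, clipped at the field border."""
    h, w = img.shape
    y0, y1 = y - _KRAD, y + _KRAD + 1
    x0, x1 = x - _KRAD, x + _KRAD + 1
    ky0, kx0 = max(0, -y0), max(0, -x0)
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(h, y1), min(w, x1)
    img[y0:y1, x0:x1] += amp * _KERNEL[ky0:ky0 + (y1 - y0), kx0:kx0 + (x1 - x0)]


def _grid(n_cells: int, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    cols = int(math.ceil(math.sqrt(n_cells * shape[1] / shape[0])))
    cols = max(1, cols)
    rows = int(math.ceil(n_cells / cols))
    tile_h, tile_w = shape[0] // rows, shape[1] // cols
    if min(tile_h, tile_w) < 80:
        raise ConfigurationError(
            f"image_shape {shape} too small for {n_cells} cells "
            f"(tile {tile_h}x{tile_w} < 80 px)"
        )
    return rows, cols, tile_h, tile_w


def _mito_walk(rng: np.random.Generator, tile: tuple[int, int],
               density: float) -> np.ndarray:
    """Stamp a persistent random walk with a disk to form a mito network mask.

    The filament half-width is chosen so that, after the standard 8-step
    dilation defines the cell footprint, mitochondria occupy roughly
    ``density`` of that footprint (for a strip: width / (width + 16)).
    """
    h, w = tile
    mask = np.zeros(tile, dtype=bool)
    width = 16.0 * density / max(1e-6, 1.0 - density)
    r_f = max(1.0, width / 2.0)
    rr = int(math.ceil(r_f))
    dy, dx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    disk = (dy ** 2 + dx ** 2) <= r_f ** 2
    lo, hi_y, hi_x = _TILE_MARGIN, h - _TILE_MARGIN, w - _TILE_MARGIN
    n_walks = 3
    # total filament length scaled to the tile so the footprint fills it loosely
    n_steps = max(20, int(0.35 * (h - 2 * _TILE_MARGIN) * (w - 2 * _TILE_MARGIN)
                          / (2.0 * max(4.0, 2 * r_f + 16)) / n_walks))
    for _ in range(n_walks):
        y = rng.uniform(0.35 * h, 0.65 * h)
        x = rng.uniform(0.35 * w, 0.65 * w)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.35)
            y += 2.0 * math.sin(ang)
            x += 2.0 * math.cos(ang)
            if not (lo + rr < y < hi_y - rr):
                y = np.clip(y, lo + rr + 1, hi_y - rr - 1)
                ang = -ang
            if not (lo + rr < x < hi_x - rr):
                x = np.clip(x, lo + rr + 1, hi_x - rr - 1)
                ang = np.pi - ang
            yi, xi = int(round(y)), int(round(x))
            mask[yi - rr:yi + rr + 1, xi - rr:xi + rr + 1] |= disk
    return mask


def _vesicle_pool_fraction(pool: float, m: float) -> float:
    """Vesicle-bound fraction of the *total* signal given the cytoplasmic
    pool fraction and the mito area fraction of the cell footprint."""
    return pool * (1.0 - m) / (1.0 - pool * m)


@dataclass
class _Scene:
    config: SimulationConfig
    cell_labels: np.ndarray
    mito_mask: np.ndarray
    vesicles: pd.DataFrame
    cells: pd.DataFrame
    diffuse: dict[str, np.ndarray]   # per marker channel, noise-free diffuse image


def _build_scene(config: SimulationConfig, rng: np.random.Generator) -> _Scene:
    h, w = config.image_shape
    rows, cols, th, tw = _grid(config.n_cells, config.image_shape)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    mito_mask = np.zeros((h, w), dtype=bool)
    diffuse = {"A": np.zeros((h, w)), "B": np.zeros((h, w))}
    n_a, n_b = config.vesicles_per_channel
    dual = round(config.overlap_fraction * n_b)
    dedicated_a = n_a - dual
    ves_rows = []
    cell_rows = []
    for cell in range(1, config.n_cells + 1):
        r, c = divmod(cell - 1, cols)
        oy, ox = r * th, c * tw
        mito_t = _mito_walk(rng, (th, tw), config.mito_density)
        cell_t = ndimage.binary_dilation(mito_t, structure=_STRUCT,
                                         iterations=_N_DILATIONS)
        m_area, c_area = int(mito_t.sum()), int(cell_t.sum())
        m = m_area / c_area
        # vesicles live in a core ring: >= 2 px from both the mito boundary and
        # the cell edge, so their rendered mass stays in the right compartment
        core = cell_t & ~ndimage.binary_dilation(mito_t, structure=_STRUCT,
                                                 iterations=2)
        core &= ndimage.binary_erosion(cell_t, structure=_STRUCT, iterations=2)
        mito_core = ndimage.binary_erosion(mito_t, structure=_STRUCT, iterations=2)
        if not mito_core.any():
            mito_core = mito_t
        cyto_idx = np.flatnonzero(core)
        mito_idx = np.flatnonzero(mito_core)
        n_ves = dedicated_a + n_b
        pos = cyto_idx[rng.integers(0, len(cyto_idx), size=n_ves)]
        cap = mito_idx[rng.integers(0, len(mito_idx), size=n_ves)]
        ys, xs = np.unravel_index(pos, (th, tw))
        yc, xc = np.unravel_index(cap, (th, tw))
        carries_a = np.zeros(n_ves, dtype=bool)
        carries_b = np.zeros(n_ves, dtype=bool)
        carries_a[:dedicated_a] = True           # dedicated A vesicles
        carries_b[dedicated_a:] = True           # all B-carrying vesicles
        carries_a[dedicated_a:dedicated_a + dual] = True   # dual vesicles
        v = {ch: _vesicle_pool_fraction(getattr(config, f"pool_fraction_{ch}"), m)
             for ch in ("A", "B")}
        s = config.signal_per_cell
        amp_a = np.where(carries_a, v["A"] * s / n_a, 0.0)
        amp_b = np.where(carries_b, v["B"] * s / n_b if n_b else 0.0, 0.0)
        for ch in ("A", "B"):
            diffuse[ch][oy:oy + th, ox:ox + tw][cell_t] += \
                (1.0 - v[ch]) * s / c_area
        reloc = carries_a if config.fkbp_channel == "A" else carries_b
        t_on = config.onset_frame * config.frame_interval
        capture_time = np.full(n_ves, np.inf)
        capture_time[reloc] = t_on + rng.exponential(config.tau_capture,
                                                     size=int(reloc.sum()))
        ves_rows.append(pd.DataFrame({
            "cell": cell, "y": ys + oy, "x": xs + ox,
            "y_cap": yc + oy, "x_cap": xc + ox,
            "carries_A": carries_a, "carries_B": carries_b,
            "amp_A": amp_a, "amp_B": amp_b,
            "relocalizable": reloc, "capture_time": capture_time,
        }))
        g = {ch: (1.0 - v[ch]) * m for ch in ("A", "B")}
        cell_rows.append({"cell": cell, "mito_area": m_area, "cell_area": c_area,
                          "v_A": v["A"], "v_B": v["B"],
                          "g_A": g["A"], "g_B": g["B"]})
        cell_labels[oy:oy + th, ox:ox + tw][cell_t] = cell
        mito_mask[oy:oy + th, ox:ox + tw] |= mito_t
    vesicles = pd.concat(ves_rows, ignore_index=True)
    cells = pd.DataFrame(cell_rows)
    return _Scene(config, cell_labels, mito_mask, vesicles, cells, diffuse)


def _render(scene: _Scene, t: float | None, rng: np.random.Generator) -> np.ndarray:
    """Render a (C, Y, X) frame of the scene at time ``t`` (``None`` = pre)."""
    cfg = scene.config
    h, w = cfg.image_shape
    img = np.zeros((3, h, w))
    for ch in ("A", "B"):
        img[CHANNEL_INDEX[ch]] = scene.diffuse[ch]
    ves = scene.vesicles
    captured = np.zeros(len(ves), dtype=bool) if t is None \
        else (ves["relocalizable"].to_numpy()
              & (ves["capture_time"].to_numpy() <= t))
    ys = np.where(captured, ves["y_cap"].to_numpy(), ves["y"].to_numpy())
    xs = np.where(captured, ves["x_cap"].to_numpy(), ves["x"].to_numpy())
    for ch in ("A", "B"):
        plane = img[CHANNEL_INDEX[ch]]
        amps = ves[f"amp_{ch}"].to_numpy()
        nz = amps > 0
        for y, x, a in zip(ys[nz], xs[nz], amps[nz]):
            _add_spot(plane, int(y), int(x), a)
    mito_plane = np.where(scene.mito_mask, cfg.mito_intensity, 0.0)
    img[CHANNEL_INDEX["mitotrap"]] = ndimage.gaussian_filter(mito_plane, 1.0)
    img += cfg.background_level
    if cfg.photon_scale > 0:
        img = rng.poisson(img * cfg.photon_scale) / cfg.photon_scale
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return img


def simulate_fixed_capture_pair(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Simulate a fixed-cell experiment: the same field pre- and post-rapalog.

    The post image shows the capture-complete state (t >> tau): every vesicle
    carrying the FKBP-tagged marker sits on the mitochondrial network.

    Returns ``(pre, post, ground_truth)`` with images of shape (3, Y, X) in
    channel order (A, B, mitotrap).
    """
    rng = np.random.default_rng(config.seed)
    scene = _build_scene(config, rng)
    pre = _render(scene, None, rng)
    post = _render(scene, math.inf, rng)
    gt = GroundTruth(config, scene.cell_labels, scene.mito_mask,
                     scene.vesicles, scene.cells)
    return pre, post, gt


def simulate_capture_timelapse(
    config: SimulationConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a capture time lapse of shape (T, 3, Y, X).

    Before ``onset_frame`` the relocalizable pool is diffuse; afterwards each
    relocalizable vesicle jumps to the mitochondrial network at an
    exponentially distributed time (mean ``tau_capture``), so the bulk
    mitochondrial signal follows ``1 - exp(-(t - t_on)/tau)``.
    """
    rng = np.random.default_rng(config.seed)
    scene = _build_scene(config, rng)
    frames = np.empty((config.n_frames, 3) + config.image_shape, dtype=np.float32)
    for i in range(config.n_frames):
        frames[i] = _render(scene, i * config.frame_interval, rng)
    gt = GroundTruth(config, scene.cell_labels, scene.mito_mask,
                     scene.vesicles, scene.cells)
    return frames, gt


def simulate_trace(
    t: np.ndarray,
    tau: float,
    f_base: float = 1.0,
    f_plateau: float = 3.0,
    t_on: float = 20.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate a delayed mono-exponential capture trace, optionally noisy.

    ``noise_sd`` is in the same units as the trace (absolute, not relative).
    """
    t = np.asarray(t, dtype=float)
    f = np.where(t < t_on, f_base,
                 f_plateau - (f_plateau - f_base) * np.exp(-(t - t_on) / tau))
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return f


# ---------------------------------------------------------------------------
# puncta stacks
# ---------------------------------------------------------------------------

def simulate_puncta_stack(
    n_puncta: int,
    volumes: list[float],
    shape: tuple[int, int, int] = (32, 96, 96),
    pixel_size: float = 0.04,
    z_step: float = 0.10,
    *,
    seed: int = 0,
    background: float = 20.0,
    amplitude: float = 200.0,
    noise_sd: float = 0.0,
    max_tries: int = 1000,
) -> tuple[np.ndarray, PunctaGroundTruth]:
    """Simulate a 3D stack containing disjoint blobs of known volume.

    Blobs are spheres in physical coordinates rendered with partial-volume
    antialiasing (each voxel's intensity is its coverage fraction, estimated
    on a 3x3x3 sub-grid), so a half-maximum threshold recovers the physical
    volume; the half-maximum voxel-count volume matches the requested volume
    to within one voxel shell.

    Raises
    ------
    ConfigurationError
        If the requested volumes cannot be placed disjointly after
        ``max_tries`` attempts, or volumes/voxel size are inconsistent.
    """
    if n_puncta != len(volumes):
        raise ConfigurationError("n_puncta must equal len(volumes)")
    vz, vy, vx = z_step, pixel_size, pixel_size
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    coverage = np.zeros(shape)
    occupied = np.zeros(shape, dtype=bool)
    vols, centers = [], []
    for i, vol in enumerate(volumes, start=1):
        r = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        if r < min(vz, vy, vx) / 4.0:
            raise ConfigurationError(
                f"volume {vol} um^3 not resolvable at voxel "
                f"({vz} x {vy} x {vx}) um")
        rz, ry, rx = (int(math.ceil(r / s)) + 1 for s in (vz, vy, vx))
        if any(2 * (rr + 2) >= s for rr, s in zip((rz, ry, rx), shape)):
            raise ConfigurationError(
                f"blob of volume {vol} um^3 does not fit in a stack of shape "
                f"{shape} at voxel ({vz} x {vy} x {vx}) um")
        placed = False
        for _ in range(max_tries):
            cz = rng.uniform(rz + 1, shape[0] - rz - 2)
            cy = rng.uniform(ry + 1, shape[1] - ry - 2)
            cx = rng.uniform(rx + 1, shape[2] - rx - 2)
            z0, y0, x0 = int(cz) - rz, int(cy) - ry, int(cx) - rx
            zz, yy, xx = np.mgrid[z0:int(cz) + rz + 1,
                                  y0:int(cy) + ry + 1,
                                  x0:int(cx) + rx + 1]
            # coverage fraction per voxel from a 3x3x3 sub-voxel grid
            sub = (np.arange(3) - 1.0) / 3.0
            cover = np.zeros(zz.shape)
            for sz in sub:
                for sy in sub:
                    for sx in sub:
                        cover += (((zz + sz - cz) * vz) ** 2 +
                                  ((yy + sy - cy) * vy) ** 2 +
                                  ((xx + sx - cx) * vx) ** 2) <= r ** 2
            cover /= 27.0
            blob = cover >= 0.5
            if not blob.any():
                continue
            region = (slice(z0, int(cz) + rz + 1),
                      slice(y0, int(cy) + ry + 1),
                      slice(x0, int(cx) + rx + 1))
            # two-voxel clearance keeps blobs disjoint after isotropic rescaling
            pad = ndimage.binary_dilation(blob, iterations=2)
            if (occupied[region] & pad).any():
                continue
            labels[region][blob] = i
            coverage[region] = np.maximum(coverage[region], cover)
            occupied[region] |= pad
            vols.append(blob.sum() * vz * vy * vx)
            centers.append((cz * vz, cy * vy, cx * vx))
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                f"could not place blob {i} disjointly after {max_tries} tries")
    stack = background + amplitude * coverage
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    gt = PunctaGroundTruth(labels, np.array(vols), np.asarray(volumes, float),
                           np.array(centers).reshape(-1, 3), (vz, vy, vx))
    return stack, gt


# ---------------------------------------------------------------------------
# LFQ tables
# ---------------------------------------------------------------------------

def simulate_lfq_experiment(
    config: LfqSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, LfqGroundTruth]:
    """Simulate a protein-group quantification table with a spiked enriched set.

    Returns
    -------
    quant : DataFrame in the tab-delimited protein-group dialect ("Protein IDs",
        "Gene names", one "LFQ intensity <condition>_R<i>" column per sample,
        contaminant/reverse flags).  Missing values are encoded as 0.
    annotations : DataFrame with per-protein ``secreted`` flags, ``tmd_count``
        and one boolean column per configured reference set.
    ground_truth : the spiked protein ids and true log2 effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(n)])
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(n, size=config.n_enriched, replace=False)] = True
    effects = np.where(
        enriched,
        rng.normal(config.log2_effect_mean, config.log2_effect_sd, size=n),
        0.0,
    )
    base = rng.normal(config.base_mean, config.base_sd, size=n)
    reps = config.n_replicates
    cols: dict[str, np.ndarray] = {}
    log2_vals: dict[str, np.ndarray] = {}
    for cond, shift in ((config.condition_a, effects), (config.condition_b, 0.0)):
        for r in range(1, reps + 1):
            log2_vals[f"{cond}_R{r}"] = base + shift + \
                rng.normal(0.0, config.replicate_sd, size=n)
    for sample, x in log2_vals.items():
        intensity = np.power(2.0, x)
        if config.dropout_midpoint is not None:
            p_drop = 1.0 / (1.0 + np.exp(
                (x - config.dropout_midpoint) / config.dropout_steepness))
            intensity = np.where(rng.random(n) < p_drop, 0.0, intensity)
        cols[f"LFQ intensity {sample}"] = intensity
    quant = pd.DataFrame({"Protein IDs": ids, "Gene names": ids, **cols})
    quant["Potential contaminant"] = ""
    quant["Reverse"] = ""
    quant["Only identified by site"] = ""
    if config.n_contaminants:
        cont = pd.DataFrame({
            "Protein IDs": [f"CON__{i}" for i in range(config.n_contaminants)],
            "Gene names": [f"CON__{i}" for i in range(config.n_contaminants)],
            **{c: np.power(2.0, rng.normal(config.base_mean, 1.0,
                                           config.n_contaminants))
               for c in cols},
        })
        cont["Potential contaminant"] = "+"
        cont["Reverse"] = ""
        cont["Only identified by site"] = ""
        quant = pd.concat([quant, cont], ignore_index=True)

    sec_p = np.where(enriched, config.secreted_prob_enriched, config.secreted_prob)
    secreted = rng.random(n) < sec_p
    tmd_p = np.where(enriched, config.tmd_prob_enriched, config.tmd_prob)
    has_tmd = rng.random(n) < tmd_p
    tmd_count = np.where(has_tmd, 1 + rng.poisson(config.tmd_mean_extra, size=n), 0)
    annotations = pd.DataFrame({"protein": ids, "secreted": secreted,
                                "tmd_count": tmd_count})
    for name, p_bg, p_enr in config.reference_sets:
        p = np.where(enriched, p_enr, p_bg)
        annotations[name] = rng.random(n) < p
    gt = LfqGroundTruth(config, list(ids[enriched]),
                        pd.Series(effects, index=ids, name="log2_effect"),
                        annotations)
    return quant, annotations, gt
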