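"""Capture kinetics, tau co-variation and vesicle pool / subset-share inference.

The mitochondrial fluorescence of a captured marker follows a delayed
mono-exponential:

    F(t) = F_base                                         for t <  t_on
    F(t) = F_plateau - (F_plateau - F_base) e^{-(t-t_on)/tau}   for t >= t_on

Fitting tau per cell and per channel lets two markers' capture kinetics be
compared (through-origin regression of tau_B on tau_A).  The sizes of the
relocalizable vesicle pools are inferred from cytoplasmic-loss percentages,
and the subset-share statistic

    share = co-relocated loss / maximal direct loss

estimates what fraction of one vesicle population carries the other marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from invkit.errors import ConfigurationError

__all__ = [
    "Trace",
    "ExpFit",
    "CovariationResult",
    "PoolEstimate",
    "fit_single_exponential",
    "tau_covariation",
    "pool_shares",
]


@dataclass
class Trace:
    """A mitochondrial fluorescence time course for one cell, one channel."""

    t: np.ndarray                    # s, strictly increasing
    f: np.ndarray                    # mito fluorescence per frame
    t_on: float                      # rapalog onset time, s
    cell_id: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape:
            raise ConfigurationError("t and f must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigurationError("t must be strictly increasing")

    @property
    def f0(self) -> float:
        """Mean pre-onset fluorescence (fluorescence at recording start if the
        onset coincides with the first frame)."""
        pre = self.f[self.t < self.t_on]
        val = float(pre.mean()) if pre.size else float(self.f[0])
        return val

    @property
    def normalized(self) -> np.ndarray:
        """F/F0 — the trace divided by the pre-onset fluorescence."""
        f0 = self.f0
        if f0 <= 0:
            raise ConfigurationError("F0 must be > 0 to normalize")
        return self.f / f0


@dataclass
class ExpFit:
    """Result of a delayed mono-exponential capture fit."""

    f_base: float
    f_plateau: float
    tau: float
    rss: float
    converged: bool
    n_points: int = 0

    @property
    def rise(self) -> float:
        return self.f_plateau - self.f_base


@dataclass
class CovariationResult:
    """Through-origin regression of paired time constants.

    ``r_squared`` is the uncentered coefficient of determination
    ``1 - sum((y - slope*x)^2) / sum(y^2)``; the centered definition is
    ill-posed for a model without an intercept.
    """

    slope: float
    r_squared: float
    n: int
    pairs: np.ndarray


@dataclass
class PoolEstimate:
    """Subset-share statistic from direct-capture and co-relocation losses."""

    max_loss: float                  # % cytoplasmic loss, direct capture
    co_loss: float                   # % cytoplasmic loss of the same marker, co-capture
    subset_share_raw: float
    subset_share: float              # clipped to [0, 1]
    full_capture: bool
    tolerance: float

    @property
    def percent(self) -> float:
        return 100.0 * self.subset_share_raw

    @property
    def percent_rounded(self) -> int:
        """Share as a percentage rounded to the nearest integer."""
        return int(round(self.percent))

    @property
    def percent_rounded_ten(self) -> int:
        """Share as a percentage rounded to the nearest ten ("~20%")."""
        return int(round(self.percent / 10.0) * 10)

    def render(self) -> str:
        if self.full_capture:
            return "full capture (entire pool trapped)"
        return f"∼{self.percent_rounded_ten}%"


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _model(t: np.ndarray, t_on: float, f_base: float, f_plateau: float,
           tau: float) -> np.ndarray:
    out = np.where(t < t_on, f_base,
                   f_plateau - (f_plateau - f_base) * np.exp(
                       -np.clip(t - t_on, 0.0, None) / tau))
    return out


def fit_single_exponential(trace: Trace, noise_floor_sds: float = 2.0) -> ExpFit:
    """Least-squares fit of the delayed mono-exponential capture model.

    Initialization is data driven: ``F_base`` from the pre-onset mean,
    ``F_plateau`` from the final 10% of frames, ``tau0`` from the time to
    half-rise.  The fit is flagged not converged when the fitted rise is
    below ``noise_floor_sds`` pre-onset standard deviations (flat or
    divergent traces).
    """
    t, f, t_on = trace.t, trace.f, trace.t_on
    post = t >= t_on
    if post.sum() < 3:
        raise ConfigurationError("need >= 3 post-onset frames to fit")
    pre = f[~post]
    f_base0 = float(pre.mean()) if pre.size else float(f[0])
    n_tail = max(1, int(round(0.1 * len(f))))
    f_plat0 = float(f[-n_tail:].mean())
    rise0 = f_plat0 - f_base0
    noise_sd = float(pre.std(ddof=1)) if pre.size > 2 else 0.0
    # tau0: first time the trace crosses half-rise after onset
    if rise0 > 0:
        half = f_base0 + 0.5 * rise0
        crossed = np.nonzero(post & (f >= half))[0]
        tau0 = float(t[crossed[0]] - t_on) / np.log(2.0) if crossed.size else \
            float(t[post][-1] - t_on) / 2.0
        tau0 = max(tau0, float(np.diff(t).min()))
    else:
        tau0 = max(1.0, float(t[-1] - t_on) / 4.0)

    def resid(p):
        return _model(t, t_on, p[0], p[1], p[2]) - f

    scale = max(abs(f_base0), abs(f_plat0), 1e-12)
    sol = least_squares(
        resid, x0=[f_base0, f_plat0, tau0],
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    f_base, f_plateau, tau = sol.x
    rss = float(np.sum(sol.fun ** 2))
    rise = f_plateau - f_base
    floor = noise_floor_sds * noise_sd
    converged = bool(sol.success and rise > max(floor, 1e-9 * scale)
                     and np.isfinite(tau) and tau > 0
                     and tau < 100.0 * (t[-1] - t_on))
    return ExpFit(float(f_base), float(f_plateau), float(tau), rss,
                  converged, n_points=len(t))


def tau_covariation(pairs) -> CovariationResult:
    """Through-origin fit of tau_B against tau_A across cells.

    slope = sum(x*y) / sum(x^2); R^2 (uncentered) = 1 - SSR / sum(y^2).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ConfigurationError("need >= 2 (tau_A, tau_B) pairs")
    if np.any(pairs <= 0):
        raise ConfigurationError("all time constants must be > 0")
    x, y = pairs[:, 0], pairs[:, 1]
    slope = float(np.sum(x * y) / np.sum(x ** 2))
    ssr = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - ssr / float(np.sum(y ** 2))
    return CovariationResult(slope=slope, r_squared=r2, n=len(x), pairs=pairs)


# ---------------------------------------------------------------------------
# pool shares
# ---------------------------------------------------------------------------

def pool_shares(max_loss: float, co_loss: float,
                tolerance: float = 0.1) -> PoolEstimate:
    """Subset-share statistic from cytoplasmic-loss percentages.

    ``max_loss`` is the loss of a marker's cytoplasmic signal when its own
    vesicles are captured (the relocalizable pool size); ``co_loss`` is the
    loss of the *same* marker when the other population is captured.  Their
    ratio estimates the fraction of the marker's vesicle pool shared with the
    other population.  Ratios >= ``1 - tolerance`` are flagged as full capture
    (the entire pool is trapped).  The statistic is scale invariant.
    """
    if max_loss <= 0:
        raise ConfigurationError("max_loss must be > 0")
    for name, v in (("max_loss", max_loss), ("co_loss", co_loss)):
        if not -100.0 <= v <= 100.0:
            raise ConfigurationError(f"{name}={v} outside [-100, 100]")
    raw = co_loss / max_loss
    clipped = float(np.clip(raw, 0.0, 1.0))
    return PoolEstimate(max_loss=max_loss, co_loss=co_loss,
                        subset_share_raw=float(raw), subset_share=clipped,
                        full_capture=bool(raw >= 1.0 - tolerance),
                        tolerance=tolerance)
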