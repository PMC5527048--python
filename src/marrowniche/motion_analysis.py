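"""Trajectory statistics: time-averaged MSD, anomalous-diffusion fits, speeds.

The motion model is the anomalous diffusion law

    MSD(τ) = 2 d K_α τ^α

with dimensionality ``d`` (the familiar ``MSD = 4 K_α t^α`` for 2D centroid
tracks), generalized diffusion coefficient ``K_α`` (µm²/min^α) and anomalous
exponent ``α``: subdiffusion below 1, Brownian motion at 1, superdiffusion
above 1.  ``α`` and ``K_α`` are estimated by an ordinary least-squares line on
the log-log MSD curve, restricted by default to the first quarter of lags
where the time average is well sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class Trajectory:
    """An evenly sampled cell track: positions in µm, frame interval in min."""

    track_id: int | str
    dt_min: float
    positions: np.ndarray  # (n_frames, d)
    excluded: bool = False  # e.g. proplatelet-forming cells, excluded upstream

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 positions")
        if self.dt_min <= 0:
            raise ValueError("frame interval must be > 0")
        if self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be 2D or 3D")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag, with the number of averaged pairs."""

    tau_min: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.tau_min = np.asarray(self.tau_min, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (np.diff(self.tau_min) > 0).all():
            raise ValueError("lags must be strictly increasing")
        if (self.msd_um2 < 0).any() or (self.n_pairs < 1).any():
            raise ValueError("MSD must be >= 0 with at least one pair per lag")


@dataclass
class AnomalousFit:
    K_alpha: float
    alpha: float
    d: int
    tau_range: tuple[float, float]
    r_squared: float
    n_lags: int

    def to_dict(self) -> dict:
        return {
            "K_alpha": self.K_alpha,
            "alpha": self.alpha,
            "d": self.d,
            "tau_range_min": list(self.tau_range),
            "r_squared": self.r_squared,
            "n_lags": self.n_lags,
        }


def time_averaged_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """MSD(kΔt) averaged over all start frames, for lags up to a fraction of the track.

    ``MSD(kΔt) = mean_i |r(i+k) − r(i)|²``; at least one lag is always
    returned.  Excluded tracks are refused.
    """
    if traj.excluded:
        raise ValueError(f"track {traj.track_id} is excluded from analysis")
    if not 0.0 < max_lag_fraction <= 1.0:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    n = traj.n_frames
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    pos = traj.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, k in enumerate(lags):
        diffs = pos[k:] - pos[:-k]
        msd[i] = np.mean(np.sum(diffs**2, axis=1))
    return MSDCurve(lags * traj.dt_min, msd, n - lags)


def fit_anomalous(curve: MSDCurve, d: int = 2, weighted: bool = False) -> AnomalousFit:
    """Least-squares line on (log τ, log MSD): slope = α, exp(intercept) = 2 d K_α.

    Zero-MSD lags carry no information on the exponent and are dropped with a
    warning; an all-zero curve (no motion) is an error.  With ``weighted``,
    lags are weighted by the number of averaged pairs.
    """
    positive = curve.msd_um2 > 0
    if not positive.any():
        raise ValueError("no motion; anomalous exponent undefined")
    if not positive.all():
        warnings.warn(
            f"dropping {int((~positive).sum())} zero-MSD lag(s) from the fit",
            stacklevel=2,
        )
    tau = curve.tau_min[positive]
    msd = curve.msd_um2[positive]
    if tau.size < 2:
        raise ValueError("need at least 2 positive-MSD lags to fit")
    x, y = np.log(tau), np.log(msd)
    w = np.sqrt(curve.n_pairs[positive].astype(float)) if weighted else None
    slope, intercept = np.polyfit(x, y, 1, w=w)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return AnomalousFit(
        K_alpha=float(np.exp(intercept) / (2 * d)),
        alpha=float(slope),
        d=d,
        tau_range=(float(tau[0]), float(tau[-1])),
        r_squared=r2,
        n_lags=int(tau.size),
    )


@dataclass
class VelocitySummary:
    speeds: np.ndarray  # µm/min, one per step
    median: float
    mean: float
    sd: float


def instantaneous_velocities(traj: Trajectory) -> VelocitySummary:
    """Per-step speeds |r(i+1) − r(i)| / Δt with median and SD."""
    steps = np.diff(traj.positions, axis=0)
    speeds = np.linalg.norm(steps, axis=1) / traj.dt_min
    return VelocitySummary(
        speeds=speeds,
        median=float(np.median(speeds)),
        mean=float(np.mean(speeds)),
        sd=float(np.std(speeds, ddof=1)) if speeds.size > 1 else 0.0,
    )


def classify_motion(alpha: float, tolerance: float = 0.1) -> str:
    """Motion class from the anomalous exponent, with a Brownian band |α−1| ≤ tol."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if abs(alpha - 1.0) <= tolerance:
        return "brownian"
    return "subdiffusion" if alpha < 1.0 else "superdiffusion"


@dataclass
class CohortReport:
    n_tracks: int
    n_excluded: int
    n_unfittable: int
    curves: list
    fits: list
    alpha_median: float
    alpha_sd: float
    K_median: float
    K_sd: float
    msd_at_reference_median: float
    msd_at_reference_sd: float
    reference_lag_min: float
    velocity_median: float
    velocity_sd: float
    motion_classes: dict

    def to_dict(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "n_excluded": self.n_excluded,
            "n_unfittable": self.n_unfittable,
            "alpha_median": self.alpha_median,
            "alpha_sd": self.alpha_sd,
            "K_median": self.K_median,
            "K_sd": self.K_sd,
            "msd_at_reference_median": self.msd_at_reference_median,
            "msd_at_reference_sd": self.msd_at_reference_sd,
            "reference_lag_min": self.reference_lag_min,
            "velocity_median_um_per_min": self.velocity_median,
            "velocity_sd_um_per_min": self.velocity_sd,
            "motion_classes": self.motion_classes,
        }


def _msd_at(curve: MSDCurve, tau: float) -> float:
    """MSD interpolated at a reference lag (log-log linear within support)."""
    if tau < curve.tau_min[0] or tau > curve.tau_min[-1]:
        return np.nan
    positive = curve.msd_um2 > 0
    if positive.sum() >= 2:
        return float(
            np.exp(
                np.interp(
                    np.log(tau),
                    np.log(curve.tau_min[positive]),
                    np.log(curve.msd_um2[positive]),
                )
            )
        )
    return float(np.interp(tau, curve.tau_min, curve.msd_um2))


def cohort_summary(
    trajs: list[Trajectory],
    d: int,
    max_lag_fraction: float,
    reference_lag: float,
) -> CohortReport:
    """Per-track MSD curves and fits plus cohort medians and pooled velocities.

    Excluded tracks (e.g. proplatelet-forming cells flagged upstream) are
    dropped and counted; tracks whose MSD is identically zero cannot be
    fitted and are counted separately.  A warning is emitted when the cohort
    mixes sub- and superdiffusive tracks, since the median exponent then falls
    between well-separated classes.
    """
    active = [t for t in trajs if not t.excluded]
    n_excluded = len(trajs) - len(active)
    if not active:
        raise ValueError(f"all {n_excluded} tracks are excluded")

    curves, fits, speeds = [], [], []
    n_unfittable = 0
    for traj in active:
        curve = time_averaged_msd(traj, max_lag_fraction)
        curves.append(curve)
        speeds.append(instantaneous_velocities(traj).speeds)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fit_anomalous(curve, d=d))
        except ValueError:
            fits.append(None)
            n_unfittable += 1

    alphas = np.array([f.alpha for f in fits if f is not None])
    ks = np.array([f.K_alpha for f in fits if f is not None])
    msd_ref = np.array([_msd_at(c, reference_lag) for c in curves])
    msd_ref = msd_ref[np.isfinite(msd_ref)]
    pooled = np.concatenate(speeds)

    classes: dict[str, int] = {"subdiffusion": 0, "brownian": 0, "superdiffusion": 0}
    for a in alphas:
        classes[classify_motion(a)] += 1
    if classes["subdiffusion"] and classes["superdiffusion"]:
        warnings.warn(
            "cohort mixes sub- and superdiffusive tracks; the median exponent "
            "falls between motion classes",
            stacklevel=2,
        )

    def med_sd(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return np.nan, np.nan
        return float(np.median(v)), (
            float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        )

    a_med, a_sd = med_sd(alphas)
    k_med, k_sd = med_sd(ks)
    m_med, m_sd = med_sd(msd_ref)
    return CohortReport(
        n_tracks=len(active),
        n_excluded=n_excluded,
        n_unfittable=n_unfittable,
        curves=curves,
        fits=fits,
        alpha_median=a_med,
        alpha_sd=a_sd,
        K_median=k_med,
        K_sd=k_sd,
        msd_at_reference_median=m_med,
        msd_at_reference_sd=m_sd,
        reference_lag_min=reference_lag,
        velocity_median=float(np.median(pooled)),
        velocity_sd=float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
        motion_classes=classes,
    )
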