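"""Mean squared displacement and self-diffusion of molecular centers of mass.

Units: MSD in pm^2 against lag times in ps; diffusion coefficients from
D = slope / 6 where 1 pm^2/ps = 1e-12 m^2/s, so a value in pm^2/ps is
numerically the coefficient in units of 1e-12 m^2/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory, com_trajectory
from .errors import ConfigError

R2_WARN_THRESHOLD = 0.98


@dataclass
class MSDCurve:
    lags_ps: np.ndarray
    msd_pm2: np.ndarray
    n_samples: np.ndarray   # (origin, molecule) samples per lag

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lag_ps,msd_pm2,n_samples\n")
            for lag, msd, n in zip(self.lags_ps, self.msd_pm2, self.n_samples):
                fh.write(f"{lag:.6f},{msd:.8f},{int(n)}\n")


@dataclass
class DiffusionEstimate:
    """Self-diffusion coefficient from the linear MSD regime.

    ``D`` is in units of 1e-12 m^2/s (numerically equal to pm^2/ps).
    """

    D: float
    slope_pm2_per_ps: float
    intercept_pm2: float
    r_squared: float
    window_ps: tuple
    warning: str | None = None

    @property
    def D_m2_per_s(self) -> float:
        return self.D * 1.0e-12

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"D_1e-12_m2_s": self.D, "slope_pm2_per_ps": self.slope_pm2_per_ps,
                       "intercept_pm2": self.intercept_pm2, "r_squared": self.r_squared,
                       "window_ps": list(self.window_ps), "warning": self.warning},
                      fh, indent=2)
            fh.write("\n")


def compute_msd(traj: Trajectory, topo: Topology, species: str,
                max_lag: float) -> MSDCurve:
    """MSD(tau) of the species' molecular centers of mass, averaged over all
    molecules and all sliding time origins (spacing one frame).

    The trajectory must be unwrapped; wrapped input raises a
    :class:`ConfigError` instructing to unwrap first.
    """
    if traj.wrapped:
        raise ConfigError(
            "compute_msd requires continuous coordinates: call ilsolv.core.unwrap first")
    dt = traj.timestep
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames >= traj.n_frames:
        raise ConfigError(
            f"max_lag={max_lag} ps spans {max_lag_frames} frames but the trajectory "
            f"has only {traj.n_frames}")
    if max_lag_frames < 1:
        raise ConfigError("max_lag must cover at least one frame spacing")
    coms = com_trajectory(traj, topo, species)       # (F, M, 3)
    n_frames, n_mols = coms.shape[:2]
    msd = np.zeros(max_lag_frames + 1)
    n_samples = np.empty(max_lag_frames + 1, dtype=np.int64)
    n_samples[0] = n_frames * n_mols
    for lag in range(1, max_lag_frames + 1):
        disp = coms[lag:] - coms[:-lag]
        msd[lag] = np.mean(np.sum(disp * disp, axis=2))
        n_samples[lag] = (n_frames - lag) * n_mols
    lags = np.arange(max_lag_frames + 1) * dt
    return MSDCurve(lags_ps=lags, msd_pm2=msd, n_samples=n_samples)


def fit_diffusion(msd: MSDCurve, window_frac: tuple = (0.1, 0.5)) -> DiffusionEstimate:
    """Unweighted least-squares line on a lag window, D = slope / 6.

    The default window (10-50% of the maximum lag) avoids the short-time
    ballistic/cage regime and the noisy tail. A fit with R^2 below 0.98
    gets a "non-diffusive regime" warning attached; the estimate is still
    returned.
    """
    lo_frac, hi_frac = window_frac
    if not (0 <= lo_frac < hi_frac <= 1):
        raise ConfigError(f"invalid window fractions {window_frac}")
    t_max = float(msd.lags_ps[-1])
    sel = (msd.lags_ps >= lo_frac * t_max) & (msd.lags_ps <= hi_frac * t_max)
    if sel.sum() < 10:
        raise ConfigError(
            f"fit window contains only {int(sel.sum())} lag points; need at least 10")
    x = msd.lags_ps[sel]
    y = msd.msd_pm2[sel]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    warning = None
    if r2 < R2_WARN_THRESHOLD:
        warning = f"non-diffusive regime: window fit R^2 = {r2:.4f}"
    d = slope / 6.0
    if d < 0:
        warning = (warning + "; " if warning else "") + "negative slope clamped to D = 0"
        d = 0.0
    return DiffusionEstimate(D=float(d), slope_pm2_per_ps=float(slope),
                             intercept_pm2=float(intercept), r_squared=r2,
                             window_ps=(float(x[0]), float(x[-1])), warning=warning)
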