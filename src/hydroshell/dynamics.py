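"""Water mobility and hydration-shell exchange kinetics.

Residence times follow the stable-state picture (SSP): a water is in the
reactant state when H-bonded to an ice-binding-surface (IBS) hydroxyl at
the time origin (3.5 A / 35 deg criterion), and has reached the product
state once its O atom goes beyond 5.3 A (0.53 nm, placed from the
site-water RDF) from every IBS hydroxyl oxygen.  The survival correlation

    C(t) = 1 - < p_R(0) p_P(t) >

is fitted with a bi-exponential C1 exp(-t/tau1) + C2 exp(-t/tau2); the
mean residence time is the amplitude-weighted tau = (C1 tau1 + C2 tau2)
/ (C1 + C2).  p_P is a first-passage (absorbing) indicator by default, so
transient recrossings inside the 5.3 A shell do not terminate a residence;
an instantaneous-indicator mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trajectory import Trajectory, minimum_image
from .hbond import Donor, HBondCriterion, RESIDENCE_CRITERION, bonded_to_hydroxyls


class DynamicsError(ValueError):
    pass


@dataclass
class StateDefinition:
    criterion: HBondCriterion = RESIDENCE_CRITERION
    product_cutoff: float = 5.3  # A from any IBS hydroxyl O

    def __post_init__(self) -> None:
        if self.product_cutoff <= self.criterion.r_cut:
            raise DynamicsError("product cutoff must exceed reactant distance cutoff")


@dataclass
class SurvivalCurve:
    times: np.ndarray   # ps, starting at 0
    c: np.ndarray       # C(t), C(0) = 1
    n_pairs: int        # contributing (origin, member) pairs
    dt: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "c": self.c})


@dataclass
class KineticsFit:
    c1: float
    tau1: float
    c2: float
    tau2: float
    tau: float          # mean residence time, ps
    residual: float

    def as_dict(self) -> dict:
        return vars(self).copy()


# ------------------------------------------------------------------------ MSD
def msd(
    positions: np.ndarray,
    max_lag: int,
    dt: float,
    boxes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Multiple-time-origin mean square displacement in A^2.

    ``positions`` is (n_frames, n_particles, 3).  If ``boxes`` is given the
    coordinates are taken as wrapped and are unwrapped via minimum-image
    frame-to-frame increments before averaging.
    """
    x = np.asarray(positions, float)
    if x.ndim == 2:
        x = x[:, None, :]
    n_frames = x.shape[0]
    if max_lag >= n_frames:
        raise DynamicsError(f"max_lag={max_lag} >= trajectory length {n_frames}")
    if boxes is not None:
        steps = np.empty_like(x)
        steps[0] = 0.0
        for t in range(1, n_frames):
            steps[t] = minimum_image(x[t] - x[t - 1], boxes[t])
        x = x[0] + np.cumsum(steps, axis=0)
    lags = np.arange(0, max_lag + 1)
    out = np.zeros(len(lags))
    for i, lag in enumerate(lags[1:], start=1):
        d = x[lag:] - x[:-lag]
        out[i] = np.mean(np.einsum("...i,...i->...", d, d))
    return pd.DataFrame({"time": lags * dt, "msd": out})


def diffusion_coefficient(
    msd_table: pd.DataFrame, fit_fraction: tuple[float, float] = (0.2, 0.8)
) -> float:
    """D in A^2/ps from the Einstein relation, slope(MSD)/6 over a lag window."""
    t = msd_table["time"].to_numpy()
    m = msd_table["msd"].to_numpy()
    lo = int(fit_fraction[0] * len(t))
    hi = max(lo + 2, int(fit_fraction[1] * len(t)))
    slope = np.polyfit(t[lo:hi], m[lo:hi], 1)[0]
    return float(slope / 6.0)


# ------------------------------------------------------------ state indicators
def _mda_box(box: np.ndarray) -> np.ndarray:
    from MDAnalysis.lib.mdamath import triclinic_box

    return triclinic_box(box[0], box[1], box[2])




def in_product_region(
    traj: Trajectory, ibs_o: np.ndarray, product_cutoff: float = 5.3
) -> np.ndarray:
    """Bool (n_frames, n_waters): water O beyond ``product_cutoff`` of all IBS O."""
    from MDAnalysis.lib.distances import capped_distance

    w = traj.waters
    ibs_o = np.asarray(ibs_o, int)
    out = np.ones((traj.n_frames, w.n_waters), bool)
    for t in range(traj.n_frames):
        pairs = capped_distance(
            traj.coords[t][w.o], traj.coords[t][ibs_o], product_cutoff,
            box=_mda_box(traj.boxes[t]), return_distances=False,
        )
        if len(pairs):
            out[t, np.unique(pairs[:, 0])] = False
    return out


# -------------------------------------------------------------------- survival
def ssp_survival(
    traj: Trajectory,
    hydroxyl: list[Donor],
    ibs_o: np.ndarray | None = None,
    state: StateDefinition | None = None,
    max_lag: int | None = None,
    origin_stride: int = 10,
    mode: str = "first_passage",
) -> SurvivalCurve:
    """Stable-state-picture survival C(t) for hydroxyl-bonded waters.

    Origins are taken every ``origin_stride`` frames over a fixed window of
    ``max_lag`` frames (so every lag sees the same origins).  ``ibs_o``
    defaults to the hydroxyl oxygens themselves.
    """
    state = state or StateDefinition()
    if mode not in ("first_passage", "instantaneous"):
        raise DynamicsError(f"unknown survival mode {mode!r}")
    if ibs_o is None:
        ibs_o = np.array([d.o for d in hydroxyl], int)
    n_frames = traj.n_frames
    if max_lag is None:
        max_lag = (n_frames - 1) // 2
    if max_lag >= n_frames:
        raise DynamicsError("max_lag exceeds trajectory length")
    origins = np.arange(0, n_frames - max_lag, origin_stride)
    bonded = bonded_to_hydroxyls(traj, hydroxyl, state.criterion, frames=origins)
    product = in_product_region(traj, ibs_o, state.product_cutoff)
    n_w = product.shape[1]

    if mode == "first_passage":
        # next_product[t, w]: first frame index >= t where water w is in product
        next_product = np.full((n_frames + 1, n_w), np.iinfo(np.int64).max)
        for t in range(n_frames - 1, -1, -1):
            next_product[t] = np.where(product[t], t, next_product[t + 1])
        exit_hist = np.zeros(max_lag + 1)
        total = 0
        for row, t0 in enumerate(origins):
            members = np.flatnonzero(bonded[row])
            if members.size == 0:
                continue
            total += members.size
            fp = next_product[t0 + 1][members] - t0  # first-passage lag, frames
            fp = fp[fp <= max_lag]
            np.add.at(exit_hist, fp, 1)
        if total == 0:
            raise DynamicsError("no reactant-state waters at any origin")
        c = 1.0 - np.cumsum(exit_hist) / total
        c[0] = 1.0
    else:
        sums = np.zeros(max_lag + 1)
        total = 0
        for row, t0 in enumerate(origins):
            members = np.flatnonzero(bonded[row])
            if members.size == 0:
                continue
            total += members.size
            sums += product[t0 : t0 + max_lag + 1][:, members].sum(axis=1)
        if total == 0:
            raise DynamicsError("no reactant-state waters at any origin")
        c = 1.0 - sums / total
        c[0] = 1.0
    times = np.arange(max_lag + 1) * traj.dt
    return SurvivalCurve(times=times, c=c, n_pairs=int(total), dt=traj.dt)


# ------------------------------------------------------------------------- fit
def _biexp(t, c1, tau1, c2, tau2):
    return c1 * np.exp(-t / tau1) + c2 * np.exp(-t / tau2)


def fit_biexponential(
    curve: SurvivalCurve | tuple[np.ndarray, np.ndarray],
    floor: float = 0.01,
) -> KineticsFit:
    """Least-squares bi-exponential fit of C(t); returns amplitudes, taus, tau.

    Points with C(t) < ``floor`` are dropped; initialisation is a two-
    segment log-linear split; timescales are reported with tau1 <= tau2 and
    tau is the amplitude-weighted mean.  The amplitude weighting makes tau
    pathologically sensitive to a vanishing-amplitude slow component fitted
    to tail noise, so a single exponential is fitted as well and kept
    whenever the second component does not genuinely improve the fit.
    """
    if isinstance(curve, SurvivalCurve):
        t, c = curve.times, curve.c
    else:
        t, c = (np.asarray(x, float) for x in curve)
    keep = c >= floor
    t, c = t[keep], c[keep]
    if len(t) < 10:
        raise DynamicsError("need at least 10 lag points to fit")
    if np.ptp(c) < 1e-12:
        raise DynamicsError("no decay in C(t)")
    t_max = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    # two-segment log-linear initial guess
    pos = c > 0
    logc = np.log(c[pos])
    tp = t[pos]
    half = max(2, len(tp) // 2)

    def seg_tau(ts, ls):
        slope = np.polyfit(ts, ls, 1)[0]
        return -1.0 / slope if slope < 0 else (ts[-1] - ts[0] + 1.0)

    tau_fast = max(seg_tau(tp[:half], logc[:half]), 1e-3)
    tau_slow = seg_tau(tp[half:], logc[half:]) if len(tp) - half >= 2 else 3 * tau_fast
    tau_slow = min(max(tau_slow, 1.1 * tau_fast), 10 * t_max)

    def single(tt, cc, tau):
        return cc * np.exp(-tt / tau)

    try:
        p_single, _ = curve_fit(
            single, t, c, p0=(c[0], tau_fast),
            bounds=([0, 1e-6], [1.5, 100 * t_max]), maxfev=20000,
        )
        res_single = float(np.sqrt(np.mean((single(t, *p_single) - c) ** 2)))
    except RuntimeError:
        p_single, res_single = None, np.inf
    try:
        popt, _ = curve_fit(
            _biexp, t, c, p0=(0.5 * c[0], tau_fast, 0.5 * c[0], tau_slow),
            bounds=([0, 1e-6, 0, 1e-6], [1.5, 100 * t_max, 1.5, 100 * t_max]),
            maxfev=20000,
        )
        res_double = float(np.sqrt(np.mean((_biexp(t, *popt) - c) ** 2)))
    except RuntimeError as exc:
        if p_single is None:
            raise DynamicsError(f"fit did not converge: {exc}") from exc
        popt, res_double = None, np.inf
    use_double = popt is not None and (
        res_double < 0.7 * res_single
        and min(popt[0], popt[2]) >= 0.02 * (popt[0] + popt[2])
    )
    if use_double:
        c1, tau1, c2, tau2 = popt
        if tau1 > tau2:
            c1, tau1, c2, tau2 = c2, tau2, c1, tau1
        residual = res_double
    else:
        if p_single is None:
            raise DynamicsError("fit did not converge")
        c1, tau1 = p_single
        c2, tau2 = 0.0, float(tau1)
        residual = res_single
    amp = c1 + c2
    if amp <= 0:
        raise DynamicsError("degenerate fit: zero total amplitude")
    tau = (c1 * tau1 + c2 * tau2) / amp
    return KineticsFit(float(c1), float(tau1), float(c2), float(tau2),
                       float(tau), residual)
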