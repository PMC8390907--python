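"""Tagged-population mean-square displacements and diffusion coefficients.

MSD(τ) = ⟨(x(t+τ) − x(t))²⟩ with both a sliding-origin time average (every
saved frame is an origin) and an ensemble average over the tagged
population.  The translational diffusion coefficient follows from an
ordinary least-squares fit of

    MSD(τ) = 6·D·τ + C

over a lag window (default 20–30 ps); the intercept C absorbs
non-diffusive short-time motion.  Shell populations are tagged at the
first analyzed frame (membership fixed thereafter — members that later
leave the shell are retained).  Wrapped-coordinate MSD uses the in-cell
coordinates verbatim: curves then saturate at long lags, the confinement
signature of a periodic cell, which is harmless inside a short fit window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .solvation_structure import proximal_distance
from .synthetic import SyntheticTrajectory
from .units import A2_PER_PS_TO_1E5_CM2_S

DEFAULT_FIT_WINDOW_PS = (20.0, 30.0)


@dataclass
class MSDCurve:
    tau: np.ndarray          # ps, strictly increasing, starts at 0
    msd: np.ndarray          # Å²
    n_tagged: int
    wrapped: bool

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


@dataclass
class DiffusionFit:
    D: float                 # Å²/ps
    C: float                 # Å²
    window: tuple[float, float]
    residual_norm: float

    @property
    def D_1e5_cm2_s(self) -> float:
        """D in the conventional 10⁻⁵ cm²/s unit."""
        return self.D * A2_PER_PS_TO_1E5_CM2_S


def tag_first_shell(traj: SyntheticTrajectory, species: str,
                    protein_species: str = "protein",
                    cutoff: float = 4.5, frame: int = 0) -> np.ndarray:
    """Atom ids of species within ``cutoff`` Å of the protein surface at t=0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sp_idx = traj.select(species)
    prot = traj.select(protein_species)
    heavy = prot[traj.elements[prot] != "H"]
    d = proximal_distance(traj.coords[frame, sp_idx], traj.coords[frame, heavy],
                          traj.box.edge_length)
    return sp_idx[d <= cutoff]


def msd(traj: SyntheticTrajectory, tagged: np.ndarray, max_lag: float,
        use_wrapped: bool = False, lag_stride: int = 1) -> MSDCurve:
    """Sliding-origin, ensemble-averaged MSD curve for the tagged atoms.

    ``max_lag`` in ps; lags are every ``lag_stride``-th saved frame up to
    it.  Unwrapped mode requires continuous coordinates; wrapped mode uses
    the in-cell coordinates verbatim.
    """
    tagged = np.asarray(tagged, dtype=int)
    if tagged.size == 0:
        raise ValueError("empty tagged set")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dt = traj.timestep
    span = (traj.n_frames - 1) * dt
    if max_lag > span + 1e-9:
        raise ValueError("max_lag exceeds the trajectory span")
    x = (traj.coords if use_wrapped else traj.get_unwrapped())[:, tagged, :]
    n_lag = int(round(max_lag / dt))
    lags = np.arange(0, n_lag + 1, lag_stride)
    out = np.empty(len(lags))
    out[0] = 0.0
    for k, lag in enumerate(lags[1:], start=1):
        disp = x[lag:] - x[:-lag]
        out[k] = float((disp ** 2).sum(axis=-1).mean())
    return MSDCurve(lags * dt, out, tagged.size, use_wrapped)


def fit_diffusion(curve: MSDCurve,
                  window: tuple[float, float] = DEFAULT_FIT_WINDOW_PS) -> DiffusionFit:
    """OLS fit MSD = 6Dτ + C restricted to the lag window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("invalid fit window")
    mask = (curve.tau >= lo - 1e-9) & (curve.tau <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 MSD points inside the fit window")
    tau, m = curve.tau[mask], curve.msd[mask]
    if np.allclose(m, 0.0):
        return DiffusionFit(0.0, 0.0, (lo, hi), 0.0)
    res = stats.linregress(tau, m)
    pred = res.slope * tau + res.intercept
    return DiffusionFit(float(res.slope) / 6.0, float(res.intercept), (lo, hi),
                        float(np.linalg.norm(m - pred)))


def shell_vs_bulk_report(replicas: list[SyntheticTrajectory], species: list[str],
                         cutoff: float = 4.5,
                         window: tuple[float, float] = DEFAULT_FIT_WINDOW_PS,
                         protein_species: str = "protein",
                         lag_stride: int = 1) -> dict:
    """Paired first-shell vs. bulk diffusion coefficients per species.

    First-shell D comes from the population tagged at t=0 (wrapped or
    unwrapped coordinates as generated); bulk D averages every member of
    the species on unwrapped coordinates.  With several replicas the SEM
    over replicas is reported next to the means.
    """
    report: dict = {}
    max_lag = window[1]
    for sp in species:
        d_shell, d_bulk = [], []
        for traj in replicas:
            tagged = tag_first_shell(traj, sp, protein_species, cutoff)
            if tagged.size == 0:
                raise ValueError(f"no {sp!r} in the first shell at t=0")
            use_wrapped = traj.wrapped and traj.unwrapped_coords is None
            c_shell = msd(traj, tagged, max_lag, use_wrapped=use_wrapped,
                          lag_stride=lag_stride)
            d_shell.append(fit_diffusion(c_shell, window).D)
            allidx = traj.select(sp)
            c_bulk = msd(traj, allidx, max_lag, use_wrapped=False,
                         lag_stride=lag_stride)
            d_bulk.append(fit_diffusion(c_bulk, window).D)
        d_shell, d_bulk = np.asarray(d_shell), np.asarray(d_bulk)
        entry = {
            "D_first_shell": float(d_shell.mean()),
            "D_bulk": float(d_bulk.mean()),
            "ratio": float(d_shell.mean() / d_bulk.mean()) if d_bulk.mean() else np.nan,
        }
        if len(replicas) > 1:
            entry["sem_first_shell"] = float(d_shell.std(ddof=1) / np.sqrt(len(d_shell)))
            entry["sem_bulk"] = float(d_bulk.std(ddof=1) / np.sqrt(len(d_bulk)))
        report[sp] = entry
    return report
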