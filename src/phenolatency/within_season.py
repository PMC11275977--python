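"""Within-season dynamics: one season of the delay systems, for any strain set.

Susceptible hosts ``s`` emerge over ``[0, tl]`` and are infected by free
parasites ``v`` at rate ``beta * s * v``.  A host infected at time ``t`` by a
strain with latency ``tau`` contributes a delay term at ``t + tau``:

* semelparous release — the surviving host releases ``alpha(tau)`` progeny at
  once and moves to the recovered class ``r``;
* iteroparous release — the surviving host enters an infectious class ``i``,
  releases progeny at rate ``alpha(tau)`` per unit time and recovers at rate
  ``gamma``.

Free parasites decay at rate ``delta`` and are absorbed by the hosts they
infect (``-beta * s * v``).  Hosts live a single season, so the pre-season
history is identically zero and delayed terms vanish for ``t < tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernels
from .params import ITEROPAROUS, SEMELPAROUS, ModelParameters, alpha_of_tau

#: default integration step (time units); delays are snapped to the grid
DEFAULT_STEP = 1e-3


class IntegrationError(RuntimeError):
    """Raised when the season integration produces an invalid state."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class SeasonState:
    """Boundary state carried between seasons."""

    season_index: int
    s_hat: float
    strain_densities: np.ndarray

    def __post_init__(self) -> None:
        self.strain_densities = np.atleast_1d(
            np.asarray(self.strain_densities, dtype=float)
        )
        if self.s_hat < 0 or np.any(self.strain_densities < 0):
            raise ValueError("season state densities must be nonnegative")


@dataclass
class SeasonTrajectory:
    """Dense within-season solution on a uniform time grid over ``[0, T]``."""

    time: np.ndarray
    s: np.ndarray
    r: np.ndarray
    v: np.ndarray  # (n_strains, n_points)
    taus: np.ndarray
    params: ModelParameters
    i: np.ndarray | None = None  # (n_strains, n_points), iteroparous only
    s_hat: float = field(default=0.0)

    @property
    def n_strains(self) -> int:
        return self.v.shape[0]

    @property
    def new_infection_rate(self) -> np.ndarray:
        """Instantaneous new-infection rate ``beta * s(t) * v_k(t)`` per strain."""
        return self.params.beta * self.s[None, :] * self.v

    def final_state(self, season_index: int) -> SeasonState:
        return SeasonState(
            season_index=season_index,
            s_hat=self.s_hat,
            strain_densities=self.v[:, -1].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, compartment, strain_id, density)."""
        frames = [
            pd.DataFrame(
                {"time": self.time, "compartment": "s", "strain_id": -1, "density": self.s}
            ),
            pd.DataFrame(
                {"time": self.time, "compartment": "r", "strain_id": -1, "density": self.r}
            ),
        ]
        for k in range(self.n_strains):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "compartment": "v",
                        "strain_id": k,
                        "density": self.v[k],
                    }
                )
            )
            if self.i is not None:
                frames.append(
                    pd.DataFrame(
                        {
                            "time": self.time,
                            "compartment": "i",
                            "strain_id": k,
                            "density": self.i[k],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _n_steps(T: float, step: float) -> int:
    return max(4, int(np.ceil(T / step)))


def simulate_season(
    state: SeasonState,
    taus: np.ndarray,
    params: ModelParameters,
    step: float = DEFAULT_STEP,
) -> SeasonTrajectory:
    """Integrate one season of the multi-strain delay system.

    Parameters
    ----------
    state
        Start-of-season boundary state: emerging cohort size ``s_hat`` and
        one starting parasite density per strain.  ``s(0) = 0``; hosts enter
        through the emergence density.
    taus
        Latency period per strain (same order as ``state.strain_densities``).
    params
        Model parameters; ``release_mode`` selects the delay system.
    step
        Target RK4 step size; each delay is rounded to a whole number of
        steps (error at most ``step / 2`` in the effective latency).

    Returns
    -------
    SeasonTrajectory
        Dense solution including per-strain parasite series and, under
        iteroparous release, the infectious-host series.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    v0 = state.strain_densities
    if taus.shape != v0.shape:
        raise ValueError(
            f"got {taus.size} latency values for {v0.size} strain densities"
        )
    if np.any(taus < 0):
        raise ValueError("latency periods must be nonnegative")

    n = _n_steps(params.T, step)
    alphas = np.array([alpha_of_tau(t, params) for t in taus], dtype=float)
    time = np.linspace(0.0, params.T, n + 1)

    if params.release_mode == SEMELPAROUS:
        status, S, R, V = _kernels.semel_season(
            state.s_hat,
            v0,
            taus,
            alphas,
            params.T,
            params.tl,
            params.beta,
            params.mu_s,
            params.mu_latent,
            params.mu_latent_recovery,
            params.mu_r,
            params.delta,
            n,
        )
        I = None
    elif params.release_mode == ITEROPAROUS:
        status, S, I, R, V = _kernels.itero_season(
            state.s_hat,
            v0,
            taus,
            alphas,
            params.T,
            params.tl,
            params.beta,
            params.mu_s,
            params.mu_latent,
            params.mu_i,
            params.mu_r,
            params.gamma,
            params.delta,
            n,
        )
    else:  # pragma: no cover - guarded by ModelParameters validation
        raise ValueError(f"unknown release mode {params.release_mode!r}")

    if status != _kernels.OK:
        raise IntegrationError(
            "season integration produced a negative state beyond tolerance",
            diagnostics={
                "season_index": state.season_index,
                "s_hat": state.s_hat,
                "taus": taus.tolist(),
                "min_s": float(S.min()),
                "min_v": float(V.min()),
            },
        )

    return SeasonTrajectory(
        time=time, s=S, r=R, v=V, i=I, taus=taus, params=params, s_hat=state.s_hat
    )


def infection_generation_count(
    traj: SeasonTrajectory,
    strain: int = 0,
    min_separation: float = 0.1,
    floor_fraction: float = 1e-3,
) -> int:
    """Number of infection generations a strain completes within the season.

    A generation is a wave of new infections whose progeny are released
    before the season ends, so waves are counted as local maxima of the
    new-infection rate ``beta * s * v`` restricted to infection times
    ``t <= T - tau`` (later infections never release within the season).
    Peaks closer than ``min_separation`` time units are merged and peaks
    below ``floor_fraction`` of the global maximum are ignored.
    """
    rate = traj.new_infection_rate[strain]
    tau = float(traj.taus[strain])
    dt = traj.time[1] - traj.time[0]
    cutoff = traj.params.T - tau
    if cutoff <= 0:
        return 0
    window = rate[traj.time <= cutoff + 0.5 * dt]
    peak = window.max() if window.size else 0.0
    if peak <= 0.0:
        return 0
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(window, height=floor_fraction * peak, distance=distance)
    count = idx.size
    # a wave already in full swing at t=0 or still rising at the cutoff has
    # its maximum on the window edge, which find_peaks never reports
    if window.size >= 2 and window[0] > window[1] and window[0] >= floor_fraction * peak:
        count += 1
    if (
        window.size >= 2
        and window[-1] > window[-2]
        and window[-1] >= floor_fraction * peak
    ):
        count += 1
    return count
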