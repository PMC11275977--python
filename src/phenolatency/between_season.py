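"""Between-season maps and multi-season iteration.

At the end of each season the surviving uninfected and ever-infected hosts
reproduce under Beverton-Holt density dependence to form the next season's
emerging cohort, and the free parasites remaining at ``t = T`` become the
next season's starting parasite population.  Ever-infected hosts retain a
fraction ``phi`` of their fecundity.  Under semelparous release the map uses
``s(T)`` and ``r(T)``; under iteroparous release currently infectious hosts
``i(T)`` also reproduce (at the reduced rate) and contribute to crowding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import BEVERTON_HOLT, ITEROPAROUS, SEMELPAROUS, ModelParameters
from .within_season import (
    DEFAULT_STEP,
    IntegrationError,
    SeasonState,
    SeasonTrajectory,
    simulate_season,
)

#: strains whose start-of-season density falls below this are extinct
EXTINCTION_THRESHOLD = 1.0


@dataclass
class SeasonSummary:
    season: int
    s_hat: float
    s_T: float
    r_T: float
    i_T: float
    v_hat: np.ndarray  # start-of-season parasite density per strain
    v_T: np.ndarray  # end-of-season parasite density per strain


@dataclass
class SeasonSeries:
    """Per-season summaries of a multi-season run (strains keep their slot;
    extinct strains continue with density zero)."""

    taus: np.ndarray
    summaries: list[SeasonSummary]
    params: ModelParameters

    def __len__(self) -> int:
        return len(self.summaries)

    @property
    def s_hat(self) -> np.ndarray:
        return np.array([s.s_hat for s in self.summaries])

    @property
    def v_hat(self) -> np.ndarray:
        """(n_seasons, n_strains) start-of-season parasite densities."""
        return np.array([s.v_hat for s in self.summaries])

    @property
    def final(self) -> SeasonSummary:
        return self.summaries[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            for k, tau in enumerate(self.taus):
                rows.append(
                    {
                        "season": s.season,
                        "strain_id": k,
                        "tau": float(tau),
                        "s_hat": s.s_hat,
                        "s_T": s.s_T,
                        "r_T": s.r_T,
                        "i_T": s.i_T,
                        "v_hat": s.v_hat[k],
                        "v_T": s.v_T[k],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AttractorReport:
    kind: str  # "fixed-point" | "cycle" | "non-converged"
    period: int | None
    terminal_s_hat: float
    terminal_v_hat: float
    residual: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "kind": self.kind,
                "period": self.period,
                "terminal_s_hat": self.terminal_s_hat,
                "terminal_v_hat": self.terminal_v_hat,
                "residual": self.residual,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def next_cohort(
    s_T: float, i_T: float, r_T: float, params: ModelParameters
) -> float:
    """Size of the next season's emerging host cohort.

    Beverton-Holt recruitment: ``sigma * (s + phi*(i) + phi*r) / (1 + rho *
    (s + i + r))`` with the ``i`` terms present only under iteroparous
    release (under semelparous release hosts are never tracked in an
    infectious class).  In fixed-cohort mode the constant ``s_hat_const`` is
    returned regardless of the season outcome.
    """
    if min(s_T, i_T, r_T) < 0:
        raise ValueError("end-of-season host densities must be nonnegative")
    if params.demography_mode != BEVERTON_HOLT:
        return params.s_hat_const
    if params.release_mode == SEMELPAROUS:
        return (
            params.sigma
            * (s_T + params.phi * r_T)
            / (1.0 + params.rho * (s_T + r_T))
        )
    return (
        params.sigma
        * (s_T + params.phi * i_T + params.phi * r_T)
        / (1.0 + params.rho * (s_T + i_T + r_T))
    )


def disease_free_cohort_factor(params: ModelParameters) -> float:
    """Fraction ``k`` of an emerging cohort still susceptible at ``t = T``
    in the absence of parasites (uniform emergence then exponential decay):
    ``k = (1 - exp(-mu_s*tl)) / (mu_s*tl) * exp(-mu_s*(T - tl))``.
    """
    m, tl, T = params.mu_s, params.tl, params.T
    return (1.0 - np.exp(-m * tl)) / (m * tl) * np.exp(-m * (T - tl))


def disease_free_fixed_point(params: ModelParameters) -> float:
    """Positive fixed point ``s_hat* = (sigma*k - 1) / (rho*k)`` of the
    composed emergence/death season and Beverton-Holt recruitment, in the
    absence of parasites.  Returns 0 if the host cannot persist."""
    k = disease_free_cohort_factor(params)
    if params.sigma * k <= 1.0:
        return 0.0
    return (params.sigma * k - 1.0) / (params.rho * k)


def run_seasons(
    initial: SeasonState,
    taus: np.ndarray,
    params: ModelParameters,
    n_seasons: int,
    step: float = DEFAULT_STEP,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    keep_final_trajectory: bool = False,
) -> tuple[SeasonSeries, SeasonTrajectory | None]:
    """Chain within-season integrations through the between-season maps.

    Strains whose start-of-season density drops below
    ``extinction_threshold`` are set extinct (density zero) and stay so.
    Returns the series of per-season summaries and, optionally, the dense
    trajectory of the last season.
    """
    if n_seasons < 1:
        raise ValueError("n_seasons must be >= 1")
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    state = SeasonState(
        season_index=initial.season_index,
        s_hat=initial.s_hat,
        strain_densities=initial.strain_densities.copy(),
    )
    summaries: list[SeasonSummary] = []
    last_traj: SeasonTrajectory | None = None
    for n in range(n_seasons):
        dens = state.strain_densities.copy()
        dens[dens < extinction_threshold] = 0.0
        state = SeasonState(state.season_index, state.s_hat, dens)
        try:
            traj = simulate_season(state, taus, params, step=step)
        except IntegrationError as err:
            err.diagnostics["season_index"] = state.season_index
            raise
        i_T = float(traj.i[:, -1].sum()) if traj.i is not None else 0.0
        summaries.append(
            SeasonSummary(
                season=state.season_index,
                s_hat=state.s_hat,
                s_T=float(traj.s[-1]),
                r_T=float(traj.r[-1]),
                i_T=i_T,
                v_hat=dens,
                v_T=traj.v[:, -1].copy(),
            )
        )
        if keep_final_trajectory and n == n_seasons - 1:
            last_traj = traj
        state = SeasonState(
            season_index=state.season_index + 1,
            s_hat=next_cohort(float(traj.s[-1]), i_T, float(traj.r[-1]), params),
            strain_densities=traj.v[:, -1].copy(),
        )
    return SeasonSeries(taus=taus, summaries=summaries, params=params), last_traj


def classify_attractor(
    series: SeasonSeries,
    burn_in: int = 400,
    tol: float = 1e-3,
    max_period: int = 40,
) -> AttractorReport:
    """Classify the long-run ecological attractor of a season series.

    Looks at the post-burn-in start-of-season parasite density (the most
    volatile variable).  If its relative fluctuation is below ``tol`` the
    attractor is a fixed point; otherwise a cycle whose period is the
    dominant positive autocorrelation lag; an aperiodic remainder is
    reported as non-converged.
    """
    if len(series) <= burn_in + 20:
        raise ValueError(
            f"series of length {len(series)} too short for burn_in={burn_in}"
        )
    v = series.v_hat[burn_in:].sum(axis=1)
    scale = np.mean(np.abs(v))
    if scale == 0.0:  # parasite extinct: host-only fixed point
        s = series.s_hat[burn_in:]
        resid = float(np.ptp(s) / max(np.mean(s), 1e-300))
        kind = "fixed-point" if resid < tol else "non-converged"
        return AttractorReport(kind, None, float(series.final.s_hat), 0.0, resid)
    resid = float(np.ptp(v) / scale)
    if resid < tol:
        return AttractorReport(
            "fixed-point",
            None,
            float(series.final.s_hat),
            float(v[-1]),
            resid,
        )
    x = v - v.mean()
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    acf = acf / acf[0]
    lags = np.arange(2, min(max_period, n // 2))
    best = int(lags[np.argmax(acf[lags])])
    # verify periodicity: shifting by the candidate period must nearly
    # reproduce the series
    shifted_err = np.max(np.abs(x[best:] - x[:-best])) / max(np.max(np.abs(x)), 1e-300)
    kind = "cycle" if acf[best] > 0.5 and shifted_err < 0.2 else "non-converged"
    return AttractorReport(
        kind if kind == "cycle" else "non-converged",
        best if kind == "cycle" else None,
        float(series.final.s_hat),
        float(v[-1]),
        resid,
    )


def equilibrate(
    taus: np.ndarray,
    params: ModelParameters,
    v0: float | np.ndarray = 1e6,
    s_hat0: float | None = None,
    step: float = DEFAULT_STEP,
    rel_tol: float = 1e-8,
    window: int = 10,
    max_seasons: int = 2000,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> tuple[SeasonState, dict]:
    """Iterate seasons until the (s_hat, v_hat) pair reaches a fixed point.

    Convergence requires the relative season-to-season change of both the
    host cohort and every surviving strain's density to stay below
    ``rel_tol`` for ``window`` consecutive seasons.  Returns the attractor
    boundary state and an info dict with keys ``converged``, ``seasons``,
    ``residual`` and ``extinct``.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    v0 = np.broadcast_to(np.atleast_1d(np.asarray(v0, dtype=float)), taus.shape).copy()
    if s_hat0 is None:
        s_hat0 = (
            disease_free_fixed_point(params)
            if params.demography_mode == BEVERTON_HOLT
            else params.s_hat_const
        )
    state = SeasonState(0, s_hat0, v0)
    streak = 0
    resid = np.inf
    for n in range(max_seasons):
        series, _ = run_seasons(
            state,
            taus,
            params,
            1,
            step=step,
            extinction_threshold=extinction_threshold,
        )
        summ = series.final
        new = SeasonState(
            n + 1,
            next_cohort(summ.s_T, summ.i_T, summ.r_T, params),
            summ.v_T.copy(),
        )
        alive = new.strain_densities >= extinction_threshold
        if not alive.any():
            return new, {
                "converged": False,
                "seasons": n + 1,
                "residual": np.inf,
                "extinct": True,
            }
        num = np.abs(new.strain_densities - state.strain_densities)
        den = np.maximum(state.strain_densities, extinction_threshold)
        resid = max(
            float(np.max(num[alive] / den[alive])),
            abs(new.s_hat - state.s_hat) / max(state.s_hat, 1.0),
        )
        streak = streak + 1 if resid < rel_tol else 0
        state = new
        if streak >= window:
            return state, {
                "converged": True,
                "seasons": n + 1,
                "residual": resid,
                "extinct": False,
            }
    return state, {
        "converged": False,
        "seasons": max_seasons,
        "residual": resid,
        "extinct": False,
    }
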