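"""Stochastic trait-substitution simulation of latency-period evolution.

A monomorphic resident is burned in for a number of seasons; thereafter a
single mutant is introduced at unit density at the start of a season, with
latency drawn from a normal kernel centred on the currently densest strain.
Further mutants follow after a fixed (optionally jittered) number of
seasons.  Strains whose start-of-season density falls below the extinction
threshold are removed permanently.  Unlike a strict trait-substitution
sequence, new mutants may arrive before earlier ones have fixed, so the
community is transiently polymorphic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .between_season import next_cohort, disease_free_fixed_point
from .params import BEVERTON_HOLT, ModelParameters
from .within_season import DEFAULT_STEP, SeasonState, simulate_season


@dataclass
class EvoRunConfig:
    """Protocol parameters of the mutant-substitution simulation."""

    initial_tau: float
    burn_in: int = 100
    seasons_between_mutants: int = 1000
    mutation_sd: float = 0.1
    extinction_threshold: float = 1.0
    max_mutants: int = 30
    seed: int = 0
    introduction_jitter: int = 0  # extra Uniform{0..jitter} seasons, 0 = off
    mutant_density: float = 1.0
    initial_density: float = 1e6
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.burn_in < 1 or self.seasons_between_mutants < 1 or self.max_mutants < 0:
            raise ValueError("season counts must be positive")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be > 0")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "initial_tau": self.initial_tau,
            "burn_in": self.burn_in,
            "seasons_between_mutants": self.seasons_between_mutants,
            "mutation_sd": self.mutation_sd,
            "extinction_threshold": self.extinction_threshold,
            "max_mutants": self.max_mutants,
            "seed": self.seed,
            "introduction_jitter": self.introduction_jitter,
            "mutant_density": self.mutant_density,
            "initial_density": self.initial_density,
            "record_every": self.record_every,
        }


@dataclass
class EvoTrace:
    """Full record of an evolutionary run."""

    records: pd.DataFrame  # season, strain_id, tau, density
    introductions: pd.DataFrame  # season, strain_id, tau, parent_tau
    final_taus: np.ndarray
    final_densities: np.ndarray
    config: EvoRunConfig
    params: ModelParameters

    @property
    def final_dominant_tau(self) -> float:
        return float(self.final_taus[int(np.argmax(self.final_densities))])

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def manifest(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "config": self.config.to_dict(),
                "params": self.params.to_dict(),
                "final_taus": self.final_taus.tolist(),
                "final_densities": self.final_densities.tolist(),
                "final_dominant_tau": self.final_dominant_tau,
                "n_introductions": int(len(self.introductions)),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def plot(self, ax=None):
        """Trait trajectory: density-weighted strain latencies over seasons."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        rec = self.records
        ax.scatter(
            rec["season"],
            rec["tau"],
            s=2,
            c=np.log10(np.maximum(rec["density"], 1.0)),
            cmap="viridis",
        )
        ax.set_xlabel("season")
        ax.set_ylabel(r"latency $\tau$")
        return ax


class BurnInExtinctionError(RuntimeError):
    """The initial resident went extinct during burn-in."""


def run_evolutionary_simulation(
    config: EvoRunConfig,
    params: ModelParameters,
    step: float = DEFAULT_STEP,
) -> EvoTrace:
    """Run the mutant-substitution protocol and return the full trace.

    With a fixed seed the run is bit-reproducible.  Mutant latencies are
    redrawn until they fall inside ``(0, T]``; ties for the densest strain
    break toward the most recently introduced one.
    """
    rng = np.random.default_rng(config.seed)
    taus = np.array([float(config.initial_tau)])
    dens = np.array([float(config.initial_density)])
    strain_ids = np.array([0])
    next_id = 1
    s_hat = (
        disease_free_fixed_point(params)
        if params.demography_mode == BEVERTON_HOLT
        else params.s_hat_const
    )

    rows: list[tuple[int, int, float, float]] = []
    intro_rows: list[tuple[int, int, float, float]] = []
    season = 0

    def record(season: int) -> None:
        if season % config.record_every == 0:
            for sid, tau, d in zip(strain_ids, taus, dens):
                rows.append((season, int(sid), float(tau), float(d)))

    def advance(n_seasons: int) -> None:
        nonlocal s_hat, taus, dens, strain_ids, season
        for _ in range(n_seasons):
            alive = dens >= config.extinction_threshold
            taus, dens, strain_ids = taus[alive], dens[alive], strain_ids[alive]
            if taus.size == 0:
                return
            state = SeasonState(season, s_hat, dens)
            traj = simulate_season(state, taus, params, step=step)
            i_T = float(traj.i[:, -1].sum()) if traj.i is not None else 0.0
            s_hat = next_cohort(float(traj.s[-1]), i_T, float(traj.r[-1]), params)
            dens = traj.v[:, -1].copy()
            season += 1
            record(season)

    record(0)
    advance(config.burn_in)
    if taus.size == 0:
        raise BurnInExtinctionError(
            f"initial resident tau={config.initial_tau} went extinct within "
            f"{config.burn_in} burn-in seasons"
        )

    for _ in range(config.max_mutants):
        # parent = densest strain, ties toward the newest strain
        order = np.lexsort((strain_ids, dens))
        parent_tau = float(taus[order[-1]])
        if config.mutation_sd == 0.0:
            new_tau = parent_tau
        else:
            new_tau = -1.0
            while not (0.0 < new_tau <= params.T):
                new_tau = float(rng.normal(parent_tau, config.mutation_sd))
        taus = np.append(taus, new_tau)
        dens = np.append(dens, config.mutant_density)
        strain_ids = np.append(strain_ids, next_id)
        intro_rows.append((season, next_id, new_tau, parent_tau))
        next_id += 1

        block = config.seasons_between_mutants
        if config.introduction_jitter > 0:
            block += int(rng.integers(0, config.introduction_jitter + 1))
        advance(block)
        if taus.size == 0:
            break

    records = pd.DataFrame(rows, columns=["season", "strain_id", "tau", "density"])
    intros = pd.DataFrame(
        intro_rows, columns=["season", "strain_id", "tau", "parent_tau"]
    )
    return EvoTrace(
        records=records,
        introductions=intros,
        final_taus=taus.copy(),
        final_densities=dens.copy(),
        config=config,
        params=params,
    )
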