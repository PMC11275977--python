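"""Evolutionary invasion analysis of the latency period trait.

A resident strain with latency ``tau_r`` is iterated to its ecological
attractor; a rare mutant with latency ``tau_m`` is then introduced at unit
density at the start of a single assay season against the frozen resident
state.  The mutant's invasion fitness is its end-of-season density
``v_m(T)`` (invasion iff ``v_m(T) >= 1``).  Because the mutant enters at
density 1 against a resident at density ``v_hat* >> 1``, it is dynamically
negligible and no explicit linearization is needed.

Singular strategies are located by bisecting sign changes of a numerical
selection gradient and classified from the local PIP geometry (ESS
attractors are uninvasible; repellors separate basins of attraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .between_season import equilibrate
from .params import ModelParameters
from .within_season import DEFAULT_STEP, SeasonState, simulate_season

#: relative band around 1 inside which a fitness value counts as neutral in
#: the gradient sign; selection near the weaker singular points is of order
#: 1e-4, while the equilibration residual keeps numerical noise near 1e-8,
#: so the band sits between the two
NEUTRAL_TOL = 1e-6

ESS_ATTRACTOR = "ESS-attractor"
REPELLOR = "repellor"
BOUNDARY_ATTRACTOR = "boundary-attractor"
OTHER = "other"


class ResidentExtinctError(RuntimeError):
    """The resident strain cannot persist at this latency value."""


class NonEquilibriumError(RuntimeError):
    """The resident attractor is not a fixed point (e.g. cycling)."""


@dataclass
class SingularPoint:
    tau: float
    classification: str  # ESS-attractor | repellor | boundary-attractor | other
    note: str = ""

    def to_dict(self) -> dict:
        return {"tau": self.tau, "classification": self.classification, "note": self.note}


@dataclass
class PIPResult:
    """Invasion-fitness grid over (resident latency, mutant latency)."""

    tau_resident: np.ndarray
    tau_mutant: np.ndarray
    fitness: np.ndarray  # (n_resident, n_mutant); NaN where resident extinct
    params: ModelParameters

    @property
    def sign(self) -> np.ndarray:
        """+1 where the mutant invades (fitness >= 1), -1 where it dies out,
        0 where the resident itself is not viable."""
        out = np.where(self.fitness >= 1.0, 1, -1)
        return np.where(np.isnan(self.fitness), 0, out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fitness, index=self.tau_resident, columns=self.tau_mutant
        ).rename_axis(index="tau_resident", columns="tau_mutant")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def plot(self, ax=None):
        """Black/white raster of the invasion regions (black = invades),
        resident latency on the x axis, mutant latency on the y axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.pcolormesh(
            self.tau_resident,
            self.tau_mutant,
            (self.sign.T > 0).astype(float),
            cmap="gray_r",
            shading="nearest",
        )
        ax.set_xlabel(r"resident latency $\tau_r$")
        ax.set_ylabel(r"mutant latency $\tau_m$")
        return ax


# -- resident equilibria, cached per (params, tau, step) ---------------------

_EQ_CACHE: dict[tuple, tuple[SeasonState, dict]] = {}


def clear_equilibrium_cache() -> None:
    _EQ_CACHE.clear()


def resident_equilibrium(
    tau_r: float,
    params: ModelParameters,
    step: float = DEFAULT_STEP,
    v0: float = 1e6,
    max_seasons: int = 2000,
) -> SeasonState:
    """Ecological attractor of a monomorphic resident with latency ``tau_r``.

    Iterates seasons from the disease-free host fixed point (or the fixed
    cohort) until the (s_hat, v_hat) pair converges.  Raises
    :class:`ResidentExtinctError` if the parasite dies out and
    :class:`NonEquilibriumError` if no fixed point is reached within the
    season cap (e.g. the attractor is a cycle).
    """
    key = (params, round(float(tau_r), 12), step, v0)
    if key in _EQ_CACHE:
        state, info = _EQ_CACHE[key]
    else:
        state, info = equilibrate(
            np.array([tau_r], dtype=float),
            params,
            v0=v0,
            step=step,
            max_seasons=max_seasons,
        )
        _EQ_CACHE[key] = (state, info)
    if info["extinct"]:
        raise ResidentExtinctError(
            f"resident with tau={tau_r:.4g} goes extinct "
            f"(season {info['seasons']})"
        )
    if not info["converged"]:
        raise NonEquilibriumError(
            f"resident with tau={tau_r:.4g} did not reach a fixed point in "
            f"{info['seasons']} seasons (residual {info['residual']:.3g}); "
            "the attractor may be a cycle"
        )
    return state


def mutant_invasion_fitness(
    tau_r: float,
    tau_m: float,
    params: ModelParameters,
    step: float = DEFAULT_STEP,
    resident_state: SeasonState | None = None,
    mutant_density: float = 1.0,
) -> float:
    """End-of-season mutant density from a unit introduction at ``t = 0``
    of one assay season against the equilibrated resident."""
    if resident_state is None:
        resident_state = resident_equilibrium(tau_r, params, step=step)
    v_hat = float(resident_state.strain_densities[0])
    assay = SeasonState(
        season_index=resident_state.season_index,
        s_hat=resident_state.s_hat,
        strain_densities=np.array([v_hat, mutant_density]),
    )
    traj = simulate_season(assay, np.array([tau_r, tau_m]), params, step=step)
    return float(traj.v[1, -1]) / mutant_density


def selection_gradient_sign(
    tau_r: float,
    params: ModelParameters,
    eps: float = 1e-2,
    step: float = DEFAULT_STEP,
    neutral_tol: float = NEUTRAL_TOL,
) -> int:
    """Sign of the local selection gradient at ``tau_r``.

    Compares invasion fitness of mutants at ``tau_r + eps`` and
    ``tau_r - eps`` (sharing one resident equilibration); returns 0 when
    both fitnesses sit inside the neutrality band around 1.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    state = resident_equilibrium(tau_r, params, step=step)
    f_up = mutant_invasion_fitness(tau_r, tau_r + eps, params, step, state)
    f_dn = mutant_invasion_fitness(tau_r, max(tau_r - eps, 0.0), params, step, state)
    if abs(f_up - 1.0) < neutral_tol and abs(f_dn - 1.0) < neutral_tol:
        return 0
    return int(np.sign(f_up - f_dn))


def _uninvasible_locally(
    tau: float,
    params: ModelParameters,
    step: float,
    offsets=(0.02, 0.05, 0.1),
) -> bool:
    state = resident_equilibrium(tau, params, step=step)
    for d in offsets:
        for tm in (tau - d, tau + d):
            if tm <= 0:
                continue
            if mutant_invasion_fitness(tau, tm, params, step, state) > 1.0 + NEUTRAL_TOL:
                return False
    return True


def find_singular_strategies(
    params: ModelParameters,
    tau_range: tuple[float, float] = (0.5, 3.8),
    coarse_n: int = 34,
    step: float = DEFAULT_STEP,
    bisect_tol: float = 5e-3,
    eps: float = 1e-2,
) -> list[SingularPoint]:
    """Locate and classify singular latency strategies in ``tau_range``.

    Scans the selection-gradient sign on a coarse grid, bisects each sign
    change to ``bisect_tol`` in tau, and classifies roots from the gradient
    geometry: a + to - change that is locally uninvasible is an ESS
    attractor, a - to + change is a repellor.  A negative gradient at the
    lowest viable grid point means selection pushes the trait to the lower
    boundary, reported as a boundary attractor (and symmetrically at the
    upper boundary).
    """
    lo, hi = tau_range
    if not (0 < lo < hi <= params.T):
        raise ValueError(f"tau_range must lie within (0, T], got {tau_range}")
    if coarse_n < 10:
        raise ValueError("coarse_n must be >= 10")
    grid = np.linspace(lo, hi, coarse_n)
    signs: list[int | None] = []
    for tau in grid:
        try:
            signs.append(selection_gradient_sign(tau, params, eps=eps, step=step))
        except (ResidentExtinctError, NonEquilibriumError):
            signs.append(None)
    viable = [(t, s) for t, s in zip(grid, signs) if s is not None]
    if not viable:
        import warnings

        warnings.warn("no viable resident anywhere in tau_range", stacklevel=2)
        return []

    points: list[SingularPoint] = []
    if viable[0][1] < 0:
        points.append(
            SingularPoint(
                tau=viable[0][0] if viable[0][0] > lo else lo,
                classification=BOUNDARY_ATTRACTOR,
                note="negative selection gradient at the lower edge of the range",
            )
        )
    if viable[-1][1] > 0:
        points.append(
            SingularPoint(
                tau=viable[-1][0] if viable[-1][0] < hi else hi,
                classification=BOUNDARY_ATTRACTOR,
                note="positive selection gradient at the upper edge of the range",
            )
        )

    for (t0, s0), (t1, s1) in zip(viable[:-1], viable[1:]):
        if s0 == 0 or s1 == 0 or s0 == s1:
            continue
        a, b, sa = t0, t1, s0
        while b - a > bisect_tol:
            mid = 0.5 * (a + b)
            try:
                sm = selection_gradient_sign(mid, params, eps=eps, step=step)
            except (ResidentExtinctError, NonEquilibriumError):
                break
            if sm == 0:
                # inside the neutral band: shrink symmetrically
                a, b = mid - 0.25 * (b - a), mid + 0.25 * (b - a)
                continue
            if sm == sa:
                a = mid
            else:
                b = mid
        root = 0.5 * (a + b)
        if s0 > 0 and s1 < 0:
            cls = (
                ESS_ATTRACTOR
                if _uninvasible_locally(root, params, step)
                else OTHER
            )
            points.append(SingularPoint(tau=root, classification=cls))
        else:
            points.append(SingularPoint(tau=root, classification=REPELLOR))

    points.sort(key=lambda p: p.tau)
    return points


def compute_pip(
    params: ModelParameters,
    tau_grid: np.ndarray,
    step: float = DEFAULT_STEP,
) -> PIPResult:
    """Invasion-fitness matrix over all (resident, mutant) latency pairs.

    Residents that cannot persist give NaN rows.  The diagonal is neutral
    (fitness 1) up to the equilibration tolerance.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid <= 0) or np.any(tau_grid > params.T):
        raise ValueError("tau_grid must lie within (0, T]")
    n = tau_grid.size
    F = np.full((n, n), np.nan)
    for i, tr in enumerate(tau_grid):
        try:
            state = resident_equilibrium(tr, params, step=step)
        except (ResidentExtinctError, NonEquilibriumError):
            continue
        for j, tm in enumerate(tau_grid):
            F[i, j] = mutant_invasion_fitness(tr, tm, params, step, state)
    return PIPResult(tau_resident=tau_grid, tau_mutant=tau_grid, fitness=F, params=params)


def singular_points_to_json(
    points: list[SingularPoint], path: str | Path | None = None
) -> str:
    text = json.dumps([p.to_dict() for p in points], indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
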