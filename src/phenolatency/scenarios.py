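"""Preset experiments: figure-style scenario presets and competition runs.

Each preset bundles a parameter set, an analysis kind and (for sweeps) the
axes to scan.  ``run_scenario`` executes the preset, writes tidy CSV/JSON
outputs plus a manifest sufficient to re-run it, and returns the results
in memory.  Sweep grids default to a reduced resolution that keeps runs at
desk scale; pass ``full_resolution=True`` for denser grids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .between_season import (
    classify_attractor,
    disease_free_fixed_point,
    next_cohort,
    run_seasons,
)
from .invasion import (
    ESS_ATTRACTOR,
    compute_pip,
    find_singular_strategies,
    singular_points_to_json,
)
from .params import (
    BEVERTON_HOLT,
    ITEROPAROUS,
    SEMELPAROUS,
    ModelParameters,
    default_parameters,
)
from .within_season import (
    DEFAULT_STEP,
    SeasonState,
    infection_generation_count,
    simulate_season,
)

log = logging.getLogger("phenolatency.scenarios")


@dataclass
class ScenarioSpec:
    """A named, fully parameterized experiment."""

    name: str
    kind: str  # PIP | singular-scan | evo-run | attractor-classify | compete | season
    params: ModelParameters
    sweep: dict[str, np.ndarray] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)

    def manifest(self) -> dict:
        from . import __version__

        return {
            "name": self.name,
            "kind": self.kind,
            "params": self.params.to_dict(),
            "sweep": {k: np.asarray(v).tolist() for k, v in self.sweep.items()},
            "options": self.options,
            "package_version": __version__,
        }


def head_to_head_dominance(
    tau_a: float,
    tau_b: float,
    params: ModelParameters,
    step: float = DEFAULT_STEP,
    v0: float = 1e3,
    max_seasons: int = 2000,
) -> dict:
    """Compete two resident strategies started at equal density.

    Both strains begin at density ``v0`` with the host at its disease-free
    attractor; seasons are iterated until one strain drops below the
    extinction threshold (``outcome = "exclusion"``, ``dominant`` = the
    surviving tau).  When the pair instead settles onto a stable two-strain
    fixed point (mutual invasibility), the run stops early with
    ``outcome = "coexistence"`` and ``dominant`` set to the strain holding
    the higher equilibrium density; an unconverged run past the season cap
    is ``"unresolved-coexistence"`` with ``dominant = None``.  The result is
    symmetric under swapping the arguments.
    """
    if tau_a == tau_b:
        return {"dominant": None, "outcome": "unresolved-identical", "seasons": 0}
    # canonical strain order so the integration is bitwise swap-symmetric
    lo, hi = sorted((float(tau_a), float(tau_b)))
    taus = np.array([lo, hi])
    dens = np.array([v0, v0])
    s_hat = (
        disease_free_fixed_point(params)
        if params.demography_mode == BEVERTON_HOLT
        else params.s_hat_const
    )
    streak = 0
    for season in range(max_seasons):
        alive = dens >= 1.0
        if alive.sum() <= 1:
            if alive.sum() == 0:
                return {"dominant": None, "outcome": "joint-extinction", "seasons": season}
            return {
                "dominant": float(taus[alive][0]),
                "outcome": "exclusion",
                "seasons": season,
            }
        traj = simulate_season(SeasonState(season, s_hat, dens), taus, params, step=step)
        i_T = float(traj.i[:, -1].sum()) if traj.i is not None else 0.0
        s_hat = next_cohort(float(traj.s[-1]), i_T, float(traj.r[-1]), params)
        new = traj.v[:, -1].copy()
        resid = float(np.max(np.abs(new - dens) / np.maximum(dens, 1.0)))
        streak = streak + 1 if resid < 1e-10 else 0
        dens = new
        if streak >= 10:
            winner = float(taus[int(np.argmax(dens))])
            return {
                "dominant": winner,
                "outcome": "coexistence",
                "seasons": season + 1,
                "densities": dens.tolist(),
                "taus": taus.tolist(),
            }
    return {"dominant": None, "outcome": "unresolved-coexistence", "seasons": max_seasons}


# -- preset registry ---------------------------------------------------------


def _fig2_pip(full: bool) -> ScenarioSpec:
    n = 60 if full else 40
    return ScenarioSpec(
        name="fig2_pip",
        kind="PIP",
        params=default_parameters(SEMELPAROUS),
        sweep={"tau": np.linspace(0.5, 3.8, n)},
    )


def _fig2_generations(full: bool) -> ScenarioSpec:
    return ScenarioSpec(
        name="fig2_generations",
        kind="season",
        params=default_parameters(SEMELPAROUS),
        options={"taus": [1.31, 2.8]},
    )


def _fig3_semelparous_bistability(full: bool) -> ScenarioSpec:
    return ScenarioSpec(
        name="fig3_semelparous_bistability",
        kind="singular-scan",
        params=default_parameters(SEMELPAROUS),
        options={"compare_tradeoff_free": True},
    )


def _fig4_iteroparous_bistability(full: bool) -> ScenarioSpec:
    return ScenarioSpec(
        name="fig4_iteroparous_bistability",
        kind="singular-scan",
        params=default_parameters(ITEROPAROUS),
        options={"compare_tradeoff_free": True},
    )


def _fig5_dominance(full: bool) -> ScenarioSpec:
    nT = 10 if full else 6
    return ScenarioSpec(
        name="fig5_dominance",
        kind="dominance-sweep",
        params=default_parameters(SEMELPAROUS),
        sweep={
            "T": np.round(np.linspace(3.0, 5.0, nT), 3),
            "tl": np.round(np.linspace(0.5, 2.0, nT), 3),
        },
        options={"modes": [SEMELPAROUS, ITEROPAROUS]},
    )


def _fig6_emergence_window(full: bool) -> ScenarioSpec:
    return ScenarioSpec(
        name="fig6_emergence_window",
        kind="dominance-sweep",
        params=default_parameters(ITEROPAROUS).replace(beta=1e-5),
        sweep={"tl": np.array([0.5, 2.0])},
        options={"modes": [ITEROPAROUS]},
    )


def _fig7_virulence(full: bool) -> ScenarioSpec:
    n = 8 if full else 5
    return ScenarioSpec(
        name="fig7_virulence",
        kind="singular-sweep",
        params=default_parameters(SEMELPAROUS),
        sweep={
            "mu_i": np.round(np.linspace(0.25, 5.0, n), 3),
            "phi": np.round(np.linspace(0.2, 1.0, n), 3),
        },
        options={"modes": [SEMELPAROUS, ITEROPAROUS]},
    )


def _fig8_cycling(full: bool) -> ScenarioSpec:
    return ScenarioSpec(
        name="fig8_cycling",
        kind="attractor-classify",
        params=default_parameters(SEMELPAROUS),
        options={
            # resident latency per mode and stressor: the ESS of the basin
            # where the stressor produces its dynamics (longer ESS under
            # high mortality, shorter ESS under strong fecundity loss)
            "taus": {
                SEMELPAROUS: {"high_mortality": 2.8, "low_fecundity": 1.31},
                ITEROPAROUS: {"high_mortality": 2.43, "low_fecundity": 0.96},
            },
            "stressors": {
                "high_mortality": {"mu_i": 5.0, "mu_r": 5.0},
                "low_fecundity": {"phi": 0.1},
            },
        },
    )


SCENARIOS: dict[str, Callable[[bool], ScenarioSpec]] = {
    "fig2_pip": _fig2_pip,
    "fig2_generations": _fig2_generations,
    "fig3_semelparous_bistability": _fig3_semelparous_bistability,
    "fig4_iteroparous_bistability": _fig4_iteroparous_bistability,
    "fig5_dominance": _fig5_dominance,
    "fig6_emergence_window": _fig6_emergence_window,
    "fig7_virulence": _fig7_virulence,
    "fig8_cycling": _fig8_cycling,
}


def get_scenario(name: str, full_resolution: bool = False) -> ScenarioSpec:
    try:
        return SCENARIOS[name](full_resolution)
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


# -- execution ---------------------------------------------------------------


def _scan_and_flag_global(params: ModelParameters, step: float) -> dict:
    """Singular-strategy scan plus head-to-head flag of the global attractor."""
    points = find_singular_strategies(params, step=step)
    attractors = [
        p for p in points if p.classification in (ESS_ATTRACTOR, "boundary-attractor")
    ]
    out: dict[str, Any] = {
        "singular_points": [p.to_dict() for p in points],
        "global_attractor": None,
    }
    if len(attractors) == 2:
        duel = head_to_head_dominance(
            attractors[0].tau, attractors[1].tau, params, step=step
        )
        out["competition"] = duel
        out["global_attractor"] = duel["dominant"]
    return out


def run_scenario(
    spec: ScenarioSpec | str,
    output_dir: str | Path = "scenario_output",
    step: float = DEFAULT_STEP,
    full_resolution: bool = False,
    make_plots: bool = True,
) -> dict:
    """Execute a scenario, writing CSV/JSON (and plots) under ``output_dir``."""
    if isinstance(spec, str):
        spec = get_scenario(spec, full_resolution)
    outdir = Path(output_dir) / spec.name
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(spec.manifest(), indent=2) + "\n")
    log.info("running scenario %s (%s)", spec.name, spec.kind)
    result: dict[str, Any] = {"name": spec.name}

    if spec.kind == "PIP":
        pip = compute_pip(spec.params, spec.sweep["tau"], step=step)
        pip.to_csv(outdir / "pip_fitness.csv")
        points = find_singular_strategies(spec.params, step=step)
        singular_points_to_json(points, outdir / "singular_points.json")
        result |= {"pip": pip, "singular_points": points}
        if make_plots:
            import matplotlib

            matplotlib.use("Agg")
            ax = pip.plot()
            ax.figure.savefig(outdir / "pip.png", dpi=150)

    elif spec.kind == "season":
        rows = []
        for tau in spec.options["taus"]:
            from .invasion import resident_equilibrium

            state = resident_equilibrium(tau, spec.params, step=step)
            traj = simulate_season(state, np.array([tau]), spec.params, step=step)
            traj.to_csv(outdir / f"season_tau{tau}.csv")
            rows.append(
                {
                    "tau": tau,
                    "generations": infection_generation_count(traj),
                    "v_T": float(traj.v[0, -1]),
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(outdir / "generations.csv", index=False)
        result["generations"] = table

    elif spec.kind == "singular-scan":
        scans = {"tradeoff": _scan_and_flag_global(spec.params, step)}
        if spec.options.get("compare_tradeoff_free"):
            scans["constant_alpha"] = _scan_and_flag_global(
                spec.params.replace(tradeoff_enabled=False), step
            )
        (outdir / "singular_scan.json").write_text(json.dumps(scans, indent=2) + "\n")
        result["scans"] = scans

    elif spec.kind in ("dominance-sweep", "singular-sweep"):
        rows = []
        for mode in spec.options.get("modes", [spec.params.release_mode]):
            base = (
                spec.params
                if spec.params.release_mode == mode
                else default_parameters(mode).replace(
                    beta=spec.params.beta, T=spec.params.T, tl=spec.params.tl
                )
            )
            for axis, values in spec.sweep.items():
                for val in values:
                    p = base.replace(**{axis: float(val)})
                    try:
                        scan = _scan_and_flag_global(p, step)
                    except Exception as err:  # keep sweeping past bad points
                        log.warning(
                            "%s sweep point %s=%s failed: %s", mode, axis, val, err
                        )
                        rows.append(
                            {"mode": mode, "axis": axis, "value": val, "error": str(err)}
                        )
                        continue
                    ess = [
                        p_["tau"]
                        for p_ in scan["singular_points"]
                        if p_["classification"] in (ESS_ATTRACTOR, "boundary-attractor")
                    ]
                    rep = [
                        p_["tau"]
                        for p_ in scan["singular_points"]
                        if p_["classification"] == "repellor"
                    ]
                    rows.append(
                        {
                            "mode": mode,
                            "axis": axis,
                            "value": float(val),
                            "ess": ess,
                            "repellors": rep,
                            "global_attractor": scan["global_attractor"],
                        }
                    )
        table = pd.DataFrame(rows)
        table.to_json(outdir / "sweep.json", orient="records", indent=2)
        result["sweep"] = table

    elif spec.kind == "attractor-classify":
        reports = {}
        for mode in (SEMELPAROUS, ITEROPAROUS):
            for stress_name, overrides in spec.options["stressors"].items():
                tau = spec.options["taus"][mode][stress_name]
                p = default_parameters(mode).replace(**overrides)
                series, _ = run_seasons(
                    SeasonState(0, disease_free_fixed_point(p), np.array([1e6])),
                    np.array([tau]),
                    p,
                    500,
                    step=step,
                )
                report = classify_attractor(series, burn_in=400)
                reports[f"{mode}:{stress_name}"] = json.loads(report.to_json())
                series.to_csv(outdir / f"series_{mode}_{stress_name}.csv")
        (outdir / "attractors.json").write_text(json.dumps(reports, indent=2) + "\n")
        result["attractors"] = reports

    else:
        raise ValueError(f"unknown scenario kind {spec.kind!r}")

    return result
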