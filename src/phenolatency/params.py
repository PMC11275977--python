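"""Model parameters, the host-emergence density and the latency trade-off.

The model describes a free-living parasite infecting a univoltine host whose
cohort emerges over a window ``[0, tl]`` at the start of each season of length
``T``.  Parasites must infect a host and release new progeny before the season
ends; progeny remaining in the environment at ``t = T`` seed the next season.

All parameters are collected in the immutable :class:`ModelParameters`
container.  Time units are deliberately unspecified (the model is generic
across disease systems); densities are absolute counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

SEMELPAROUS = "semelparous"
ITEROPAROUS = "iteroparous"
RELEASE_MODES = (SEMELPAROUS, ITEROPAROUS)

BEVERTON_HOLT = "beverton-holt"
FIXED_COHORT = "fixed-cohort"
DEMOGRAPHY_MODES = (BEVERTON_HOLT, FIXED_COHORT)


class ParameterError(ValueError):
    """Raised when a parameter set fails validation."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate and shape constants of the seasonal host-parasite model.

    Parameters
    ----------
    T
        Season length (time).
    tl
        Length of the host emergence window (time), ``0 < tl <= T``.
    beta
        Transmission rate (per parasite per time).
    alpha_const
        Number of parasites released per infection when the latency
        trade-off is disabled.
    b
        Scale of the latency trade-off ``alpha(tau) = b (tau + 0.5)^0.8``.
    delta
        Environmental decay rate of free parasites (per time).
    mu_s, mu_i, mu_r
        Death rates of susceptible, infectious and recovered hosts
        (per time).
    gamma
        Recovery rate of infectious hosts (per time; iteroparous release
        only).
    sigma
        Host fecundity (offspring per surviving host).
    rho
        Density-dependence parameter of the Beverton-Holt recruitment map
        (per host).
    phi
        Fecundity retained by ever-infected hosts, as a multiplier in
        ``[0, 1]`` (1 = no fecundity cost of infection).
    s_hat_const
        Size of the emerging host cohort when demography is decoupled
        (``demography_mode = "fixed-cohort"``).
    release_mode
        ``"semelparous"`` (all progeny released at once, a fixed delay tau
        after infection) or ``"iteroparous"`` (progeny released at constant
        rate from an infectious stage entered tau after infection).
    tradeoff_enabled
        Whether progeny number increases with latency; if False,
        ``alpha_const`` is used for every tau.
    demography_mode
        ``"beverton-holt"`` (host cohort fed back between seasons) or
        ``"fixed-cohort"``.
    latency_survival_rate
        Mortality rate applied to latent hosts in the progeny-producing
        delayed term (semelparous release, or entry into the iteroparous
        infectious class); survival is ``exp(-rate * tau)``.  ``None``
        defaults to ``mu_s``.
    recovery_survival_rate
        Mortality rate applied to latent hosts in the semelparous
        recovered-class recruitment term.  ``None`` defaults to ``mu_i``
        (hosts that die of background mortality during latency release no
        parasites and never reach ``r``).
    """

    T: float = 4.0
    tl: float = 1.0
    beta: float = 1e-7
    alpha_const: float | None = 200.0
    b: float | None = 75.0
    delta: float = 1.0
    mu_s: float = 0.25
    mu_i: float = 0.25
    mu_r: float = 0.25
    gamma: float = 3.0
    sigma: float = 200.0
    rho: float = 1e-4
    phi: float = 0.5
    s_hat_const: float = 1e7
    release_mode: str = SEMELPAROUS
    tradeoff_enabled: bool = True
    demography_mode: str = BEVERTON_HOLT
    latency_survival_rate: float | None = None
    recovery_survival_rate: float | None = None

    def __post_init__(self) -> None:
        if self.release_mode not in RELEASE_MODES:
            raise ParameterError(
                f"unknown release_mode {self.release_mode!r}; "
                f"expected one of {RELEASE_MODES}"
            )
        if self.demography_mode not in DEMOGRAPHY_MODES:
            raise ParameterError(
                f"unknown demography_mode {self.demography_mode!r}; "
                f"expected one of {DEMOGRAPHY_MODES}"
            )
        if self.beta < 0:
            raise ParameterError(f"beta must be nonnegative, got {self.beta}")
        positives = {
            "T": self.T,
            "tl": self.tl,
            "delta": self.delta,
            "mu_s": self.mu_s,
            "mu_i": self.mu_i,
            "mu_r": self.mu_r,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "rho": self.rho,
            "s_hat_const": self.s_hat_const,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if not 0.0 <= self.phi <= 1.0:
            raise ParameterError(f"phi must lie in [0, 1], got {self.phi}")
        if self.tl > self.T:
            raise ParameterError(
                f"emergence window tl={self.tl} cannot exceed season length T={self.T}"
            )
        if self.tradeoff_enabled:
            if self.b is None or not self.b > 0:
                raise ParameterError("tradeoff_enabled requires a positive b")
        else:
            if self.alpha_const is None or not self.alpha_const > 0:
                raise ParameterError(
                    "tradeoff disabled requires a positive alpha_const"
                )
        for name in ("latency_survival_rate", "recovery_survival_rate"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ParameterError(f"{name} must be nonnegative")

    # -- derived accessors -------------------------------------------------

    @property
    def mu_latent(self) -> float:
        """Mortality rate discounting the progeny-producing delayed term
        (semelparous release / iteroparous infectious entry); ``mu_s``
        unless overridden."""
        if self.latency_survival_rate is not None:
            return self.latency_survival_rate
        return self.mu_s

    @property
    def mu_latent_recovery(self) -> float:
        """Mortality rate discounting the semelparous recovered-class
        recruitment; ``mu_i`` unless overridden."""
        if self.recovery_survival_rate is not None:
            return self.recovery_survival_rate
        return self.mu_i

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a new parameter set with ``changes`` applied."""
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Read parameters from a YAML or JSON mapping."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)


def default_parameters(release_mode: str = SEMELPAROUS) -> ModelParameters:
    """Baseline parameter set (the published table's figure defaults).

    T=4, tl=1, beta=1e-7, delta=1, mu_s=mu_i=mu_r=0.25, gamma=3, sigma=200,
    rho=1e-4, phi=0.5, fixed cohort 1e7 when demography is decoupled, with the
    latency trade-off enabled at b=75 (semelparous) or b=200 (iteroparous).
    The trade-off-free release number alpha_const is 200 (semelparous) or
    400 (iteroparous), matching the constant-alpha comparisons.
    """
    if release_mode == SEMELPAROUS:
        return ModelParameters(release_mode=SEMELPAROUS, b=75.0, alpha_const=200.0)
    if release_mode == ITEROPAROUS:
        return ModelParameters(release_mode=ITEROPAROUS, b=200.0, alpha_const=400.0)
    raise ParameterError(
        f"unknown release_mode {release_mode!r}; expected one of {RELEASE_MODES}"
    )


def alpha_of_tau(tau: float, params: ModelParameters) -> float:
    """Number of parasite progeny released per infection of latency ``tau``.

    With the trade-off enabled this is ``b * (tau + 0.5)**0.8`` (longer
    incubation yields more progeny); otherwise the constant ``alpha_const``.
    """
    if tau < 0:
        raise ParameterError(f"latency tau must be nonnegative, got {tau}")
    if params.tradeoff_enabled:
        return params.b * (tau + 0.5) ** 0.8
    return params.alpha_const


def emergence_rate(t: float, tl: float, T: float | None = None) -> float:
    """Per-capita host emergence rate ``g(t, tl)`` at within-season time ``t``.

    Hosts emerge uniformly over ``[0, tl]`` at rate ``1/tl``, so the density
    integrates to one over the season.
    """
    if t < 0 or (T is not None and t > T):
        raise ParameterError(f"time t={t} outside the season")
    return 1.0 / tl if t <= tl else 0.0
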