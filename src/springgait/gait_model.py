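"""Temporal and spring-mass variables of running gait.

The runner is abstracted as a point mass bouncing on a massless leg spring.
During stance the vertical ground reaction force is approximated by a half
sine wave, which lets every spring-mass quantity be derived in closed form
from the ground contact time ``t_c``, the flight time ``t_f``, body mass,
leg length and running speed:

* peak vertical force      ``Fmax = m * g * (pi / 2) * (t_f / t_c + 1)``
* CoM stance displacement  ``dz   = Fmax * t_c**2 / (m * pi**2) - g * t_c**2 / 8``
* maximal leg compression  ``dL   = L - sqrt(L**2 - (s * t_c / 2)**2) + dz``
* leg stiffness            ``k_leg = Fmax / dL``

All quantities are strict SI (seconds, metres, newtons); unit conversion to
reporting conventions (ms, cm, kN/m) happens at I/O boundaries only.

The inverse direction — recovering ``(t_c, t_f)`` from target ``Fmax`` and
``dL`` — has a closed form for the timing ratio plus a one-dimensional
root-find, and is what calibrates the cohort simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationInfeasibleError, InvalidInputError, ModelDomainError

__all__ = [
    "LEG_LENGTH_RATIO",
    "ModelConfig",
    "StepTiming",
    "Anthropometrics",
    "TemporalVars",
    "SpringMassVariables",
    "leg_length",
    "temporal_vars",
    "spring_mass",
    "spring_mass_arrays",
    "invert_timings",
]

#: Leg length as a fraction of body height when not measured directly.
LEG_LENGTH_RATIO = 0.53


@dataclass(frozen=True)
class ModelConfig:
    """Physical constants of the forward model.

    Parameters
    ----------
    g : float
        Gravitational acceleration in m/s**2. Defaults to the sport-science
        convention of 9.81.
    """

    g: float = 9.81

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise InvalidInputError(f"g must be positive, got {self.g}")


@dataclass(frozen=True)
class StepTiming:
    """One (contact time, flight time) observation, in seconds.

    ``t_f = 0`` is admitted as the walking boundary even though runners
    always have a flight phase.
    """

    t_c: float
    t_f: float

    def __post_init__(self) -> None:
        if not self.t_c > 0:
            raise InvalidInputError(f"t_c must be positive, got {self.t_c}")
        if self.t_f < 0:
            raise InvalidInputError(f"t_f must be non-negative, got {self.t_f}")


@dataclass(frozen=True)
class Anthropometrics:
    """Body mass (kg), height (m) and leg length (m).

    Leg length defaults to ``LEG_LENGTH_RATIO * height`` but a directly
    measured value may be supplied instead.
    """

    mass: float
    height: float
    leg_length: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise InvalidInputError(f"mass must be positive, got {self.mass}")
        if not self.height > 0:
            raise InvalidInputError(f"height must be positive, got {self.height}")
        if math.isnan(self.leg_length):
            object.__setattr__(self, "leg_length", LEG_LENGTH_RATIO * self.height)
        elif not self.leg_length > 0:
            raise InvalidInputError(
                f"leg_length must be positive, got {self.leg_length}"
            )


class TemporalVars(NamedTuple):
    """Step frequency (Hz), swing time (s) and duty factor (fraction)."""

    sf: float
    t_s: float
    df: float


@dataclass(frozen=True)
class SpringMassVariables:
    """Full derived bundle at one speed (SI units)."""

    sf: float
    t_s: float
    df: float
    fmax: float
    delta_z: float
    delta_l: float
    k_leg: float


def leg_length(height: float) -> float:
    """Estimate leg length (m) as a fixed fraction of body height (m)."""
    if not height > 0:
        raise InvalidInputError(f"height must be positive, got {height}")
    return LEG_LENGTH_RATIO * height


def temporal_vars(t: StepTiming) -> TemporalVars:
    """Step frequency, swing time and duty factor from one step timing.

    ``SF = 1 / (t_c + t_f)``; ``t_s = 2 * t_f + t_c`` (two consecutive
    flight phases plus one contact of the contralateral foot);
    ``DF = t_c / (t_c + t_s) = t_c / (2 * (t_c + t_f))``.
    """
    step = t.t_c + t.t_f
    if step <= 0:
        raise InvalidInputError("t_c + t_f must be positive")
    t_s = 2.0 * t.t_f + t.t_c
    return TemporalVars(sf=1.0 / step, t_s=t_s, df=t.t_c / (t.t_c + t_s))


def spring_mass_arrays(
    t_c,
    t_f,
    mass,
    leg_len,
    speed,
    g: float = 9.81,
) -> dict[str, np.ndarray]:
    """Vectorised forward model over numpy-broadcastable inputs.

    Returns a dict with keys ``sf, ts, df, fmax, dz, dl, kleg`` (SI units).
    Raises :class:`ModelDomainError` if any element has
    ``speed * t_c / 2 >= leg_len`` or a non-positive leg compression.
    """
    t_c = np.asarray(t_c, dtype=float)
    t_f = np.asarray(t_f, dtype=float)
    mass = np.asarray(mass, dtype=float)
    leg_len = np.asarray(leg_len, dtype=float)
    speed = np.asarray(speed, dtype=float)

    if np.any(t_c <= 0) or np.any(t_f < 0):
        raise InvalidInputError("require t_c > 0 and t_f >= 0")
    if np.any(mass <= 0) or np.any(leg_len <= 0) or np.any(speed <= 0):
        raise InvalidInputError("require positive mass, leg length and speed")

    half_span = speed * t_c / 2.0
    if np.any(half_span >= leg_len):
        raise ModelDomainError(
            "leg compression undefined for this timing/speed/leg-length combination"
        )

    sf = 1.0 / (t_c + t_f)
    ts = 2.0 * t_f + t_c
    df = t_c / (t_c + ts)
    fmax = mass * g * (np.pi / 2.0) * (t_f / t_c + 1.0)
    dz = fmax * t_c**2 / (mass * np.pi**2) - g * t_c**2 / 8.0
    dl = leg_len - np.sqrt(leg_len**2 - half_span**2) + dz
    if np.any(dl <= 0):
        raise ModelDomainError("non-positive leg compression")
    kleg = fmax / dl
    return {"sf": sf, "ts": ts, "df": df, "fmax": fmax, "dz": dz, "dl": dl, "kleg": kleg}


def spring_mass(
    t: StepTiming,
    a: Anthropometrics,
    speed: float,
    cfg: ModelConfig = ModelConfig(),
) -> SpringMassVariables:
    """Forward spring-mass model for one observation.

    ``k_leg * delta_l`` equals ``fmax`` to machine precision by construction.
    """
    if not speed > 0:
        raise InvalidInputError(f"speed must be positive, got {speed}")
    out = spring_mass_arrays(t.t_c, t.t_f, a.mass, a.leg_length, speed, g=cfg.g)
    return SpringMassVariables(
        sf=float(out["sf"]),
        t_s=float(out["ts"]),
        df=float(out["df"]),
        fmax=float(out["fmax"]),
        delta_z=float(out["dz"]),
        delta_l=float(out["dl"]),
        k_leg=float(out["kleg"]),
    )


def invert_timings(
    fmax_target: float,
    delta_l_target: float,
    mass: float,
    speed: float,
    leg_len: float,
    cfg: ModelConfig = ModelConfig(),
) -> StepTiming:
    """Recover the (t_c, t_f) that reproduces target peak force and compression.

    The peak-force equation fixes the timing ratio in closed form,
    ``t_f / t_c = fmax_target / (m * g * pi / 2) - 1``; leg compression is then
    strictly increasing in ``t_c`` on the admissible interval
    ``(0, 2 * leg_len / speed)``, so a bracketed root-find on the compression
    residual pins ``t_c`` down uniquely.

    Raises
    ------
    InvalidInputError
        If ``fmax_target`` is below the zero-flight floor ``m * g * pi / 2``.
    CalibrationInfeasibleError
        If no ``t_c`` in the admissible interval attains the target compression.
    """
    if not (mass > 0 and speed > 0 and leg_len > 0):
        raise InvalidInputError("require positive mass, speed and leg length")
    if not delta_l_target > 0:
        raise InvalidInputError(
            f"delta_l_target must be positive, got {delta_l_target}"
        )
    floor = mass * cfg.g * math.pi / 2.0
    if fmax_target < floor:
        raise InvalidInputError(
            f"fmax_target {fmax_target:.6g} N is below the zero-flight floor "
            f"{floor:.6g} N"
        )
    ratio = fmax_target / floor - 1.0  # = t_f / t_c

    # dz coefficient is positive whenever fmax >= floor, so dl is monotone in t_c
    dz_coeff = fmax_target / (mass * math.pi**2) - cfg.g / 8.0

    def residual(t_c: float) -> float:
        geom = leg_len - math.sqrt(max(leg_len**2 - (speed * t_c / 2.0) ** 2, 0.0))
        return geom + dz_coeff * t_c**2 - delta_l_target

    t_max = 2.0 * leg_len / speed
    lo = 1e-9 * t_max
    hi = t_max * (1.0 - 1e-12)
    if residual(lo) > 0.0 or residual(hi) < 0.0:
        raise CalibrationInfeasibleError(
            f"no contact time in (0, {t_max:.4g}) s attains a leg compression of "
            f"{delta_l_target:.6g} m at Fmax={fmax_target:.6g} N, mass={mass:.6g} kg, "
            f"speed={speed:.6g} m/s, leg length={leg_len:.6g} m"
        )
    t_c = brentq(residual, lo, hi, xtol=1e-15, rtol=8.882e-16, maxiter=200)
    return StepTiming(t_c=float(t_c), t_f=float(ratio * t_c))
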