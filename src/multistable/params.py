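"""Parameter containers for the two-population rate model.

The model describes two neural populations coding for the two appearances of
an ambiguous display.  Each population is driven by a common input ``I0``,
inhibits the other with gain ``beta``, adapts with strength ``phi_a`` on the
slow time scale ``tau_a``, and receives independent Ornstein-Uhlenbeck noise
of standard deviation ``sigma_n`` and correlation time ``tau_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .errors import InvalidParameterError

__all__ = ["ModelParams", "SimProtocol", "InputModulation"]

#: default asymmetric initial condition (r1, r2, a1, a2) used to probe the
#: noiseless dynamical regime: population 2 starts fully active and adapted,
#: population 1 at rest.
ASYMMETRIC_INIT: Tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the competition-adaptation-noise rate model.

    Parameters
    ----------
    beta : float
        Cross-inhibition gain (dimensionless).
    phi_a : float
        Adaptation strength (dimensionless).
    i0 : float
        Common input drive to both populations (dimensionless).
    sigma_n : float
        Standard deviation of the Ornstein-Uhlenbeck noise (dimensionless).
    tau_a : float
        Adaptation time constant in seconds.
    tau_r : float
        Population-rate time constant in seconds (default 10 ms).
    tau_n : float
        Noise correlation time in seconds (default 100 ms).
    k : float
        Steepness of the logistic gain function (default 0.1).
    alpha : float
        Self-excitation gain; fixed at 0 (no self-sustaining activity).
    """

    beta: float
    phi_a: float
    i0: float
    sigma_n: float = 0.0
    tau_a: float = 1.0
    tau_r: float = 0.010
    tau_n: float = 0.100
    k: float = 0.1
    alpha: float = 0.0

    def __post_init__(self):
        for name in ("tau_a", "tau_r", "tau_n"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if self.sigma_n < 0:
            raise InvalidParameterError(f"sigma_n must be >= 0, got {self.sigma_n}")
        for name in ("beta", "phi_a", "i0"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InputModulation:
    """Anti-phase sinusoidal input modulation.

    Inputs become ``I1 = I0 + dI*cos(2*pi*t/period)`` and
    ``I2 = I0 - dI*cos(2*pi*t/period)``.
    """

    amplitude: float
    period: float

    def __post_init__(self):
        if self.period <= 0:
            raise InvalidParameterError(f"modulation period must be > 0, got {self.period}")
        if self.amplitude < 0:
            raise InvalidParameterError(f"modulation amplitude must be >= 0")


@dataclass(frozen=True)
class SimProtocol:
    """How to integrate the model: duration, step, seed, initial state.

    ``dt`` must resolve the fastest time scale: it is required to be at most
    ``tau_r / 5``; the package default is 1 ms (``tau_r / 10``).
    """

    duration: float
    dt: float = 0.001
    seed: int = 0
    initial_state: Tuple[float, float, float, float] = ASYMMETRIC_INIT
    modulation: Optional[InputModulation] = None

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if len(self.initial_state) != 4:
            raise InvalidParameterError("initial_state must be (r1, r2, a1, a2)")

    def validate_against(self, params: ModelParams) -> None:
        if self.dt > params.tau_r / 5:
            raise InvalidParameterError(
                f"dt={self.dt} too coarse for tau_r={params.tau_r}; need dt <= tau_r/5"
            )
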