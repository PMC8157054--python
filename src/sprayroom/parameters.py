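"""Flow and emission parameter containers.

Units throughout the package: hours (time), m^3 (volume), mg (mass),
mg m^-3 (concentration), h^-1 (rates), m^3 h^-1 (flows).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .grid import WHOLE_ROOM

INSTANTANEOUS = "instantaneous"
CONSTANT_RATE = "constant_rate"


@dataclass(frozen=True)
class FlowParameters:
    """Chamber ventilation and inter-compartment exchange parameters.

    Parameters
    ----------
    volume : float
        Chamber volume V in m^3.
    air_change_rate : float
        Air change rate (ACR) lambda in h^-1; the ventilation flow is
        Q = V * lambda.
    lambda_ex : float
        First-order exchange rate between adjacent compartments, h^-1.  The
        corresponding pairwise flow is Q_ex = (V/8) * lambda_ex, equal for
        all adjacent pairs and independent of lambda.
    """

    volume: float = 30.0
    air_change_rate: float = 1.0
    lambda_ex: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"chamber volume must be positive, got {self.volume}")
        if self.air_change_rate < 0:
            raise ValueError("air change rate must be non-negative")
        if self.lambda_ex < 0:
            raise ValueError("lambda_ex must be non-negative")

    @property
    def q(self) -> float:
        """Ventilation flow Q = V * lambda, m^3 h^-1."""
        return self.volume * self.air_change_rate

    @property
    def q_ex(self) -> float:
        """Pairwise exchange flow Q_ex = (V/8) * lambda_ex, m^3 h^-1."""
        return self.volume / 8.0 * self.lambda_ex

    @property
    def compartment_volume(self) -> float:
        """Volume of one of the eight compartments, m^3."""
        return self.volume / 8.0

    def with_lambda_ex(self, lambda_ex: float) -> "FlowParameters":
        return replace(self, lambda_ex=lambda_ex)


@dataclass(frozen=True)
class EmissionEvent:
    """A chemical release into the room.

    Parameters
    ----------
    source : str
        Compartment label receiving the release, or :data:`WHOLE_ROOM` for
        the well-mixed model.
    mass : float
        Total emitted chemical mass, mg.
    mode : str
        ``"instantaneous"`` (a state jump at ``start_time``) or
        ``"constant_rate"`` (mass released uniformly over ``duration``).
    duration : float or None
        Release duration in hours; required for constant-rate mode.
    start_time : float
        Release start, hours.
    """

    source: str = WHOLE_ROOM
    mass: float = 0.0
    mode: str = INSTANTANEOUS
    duration: float | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("emitted mass must be non-negative")
        if self.mode not in (INSTANTANEOUS, CONSTANT_RATE):
            raise ValueError(f"unknown emission mode {self.mode!r}")
        if self.mode == CONSTANT_RATE and (self.duration is None or self.duration <= 0):
            raise ValueError("constant_rate emission requires a positive duration")

    @property
    def rate(self) -> float:
        """Release rate during the active window, mg h^-1 (0 if instantaneous)."""
        if self.mode == CONSTANT_RATE:
            return self.mass / self.duration  # type: ignore[operator]
        return 0.0

    @property
    def end_time(self) -> float:
        if self.mode == CONSTANT_RATE:
            return self.start_time + self.duration  # type: ignore[operator]
        return self.start_time
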