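"""Time-dependent force protocols.

A :class:`DriveProtocol` maps time to a vector of applied forces.  Protocols
are piecewise continuous; the times at which they jump are declared up front
so that ODE and PDE integrators can stop and restart across each jump instead
of thrashing their step-size control through a discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["DriveProtocol"]


@dataclass(frozen=True)
class DriveProtocol:
    """Applied forces as a function of time.

    Parameters
    ----------
    kind
        One of ``constant``, ``step``, ``square_wave``, ``smooth_periodic``,
        ``custom``.
    levels
        Force vectors the protocol moves between (each an array of length d).
    switch_times
        Ordered times of discontinuity.  Empty for continuous protocols.
    period
        Period for the periodic kinds.
    ramp_fraction
        For ``smooth_periodic``: fraction of each half-period spent ramping
        between the two levels with a cosine profile.
    func
        Evaluation function for ``custom`` protocols.
    """

    kind: str
    levels: tuple = ()
    switch_times: tuple = ()
    period: float | None = None
    ramp_fraction: float = 0.5
    func: Callable[[float], np.ndarray] | None = field(default=None, compare=False)

    # ------------------------------------------------------------------ build
    @classmethod
    def constant(cls, alpha) -> "DriveProtocol":
        return cls(kind="constant", levels=(np.asarray(alpha, dtype=float),))

    @classmethod
    def step(cls, alpha_before, alpha_after, t_switch: float = 0.0) -> "DriveProtocol":
        """Abrupt change from ``alpha_before`` to ``alpha_after`` at ``t_switch``."""
        return cls(
            kind="step",
            levels=(np.asarray(alpha_before, float), np.asarray(alpha_after, float)),
            switch_times=(float(t_switch),),
        )

    @classmethod
    def square_wave(cls, alpha_a, alpha_b, period: float, t_start: float = 0.0,
                    n_periods: int = 64) -> "DriveProtocol":
        """Alternate between two levels, half a period each, starting at level a."""
        if period <= 0:
            raise ValueError("period must be positive")
        switches = tuple(t_start + 0.5 * period * k for k in range(1, 2 * n_periods))
        return cls(
            kind="square_wave",
            levels=(np.asarray(alpha_a, float), np.asarray(alpha_b, float)),
            switch_times=switches,
            period=float(period),
        )

    @classmethod
    def smooth_periodic(cls, alpha_a, alpha_b, period: float,
                        ramp_fraction: float = 0.5) -> "DriveProtocol":
        """Continuous periodic drive between two levels.

        Each half-period holds a level and ramps to the other with a cosine
        profile over ``ramp_fraction`` of the half-period.  ``ramp_fraction=1``
        gives a pure cosine oscillation (no plateaus).
        """
        if period <= 0:
            raise ValueError("period must be positive")
        if not 0 < ramp_fraction <= 1:
            raise ValueError("ramp_fraction must be in (0, 1]")
        return cls(
            kind="smooth_periodic",
            levels=(np.asarray(alpha_a, float), np.asarray(alpha_b, float)),
            period=float(period),
            ramp_fraction=float(ramp_fraction),
        )

    @classmethod
    def custom(cls, func: Callable[[float], np.ndarray],
               switch_times: Sequence[float] = ()) -> "DriveProtocol":
        return cls(kind="custom", func=func,
                   switch_times=tuple(float(t) for t in switch_times))

    # --------------------------------------------------------------- evaluate
    def __call__(self, t: float) -> np.ndarray:
        return self.evaluate(t)

    def evaluate(self, t: float) -> np.ndarray:
        if self.kind == "constant":
            return self.levels[0]
        if self.kind == "step":
            return self.levels[1] if t >= self.switch_times[0] else self.levels[0]
        if self.kind == "square_wave":
            phase = (t % self.period) / self.period
            return self.levels[0] if phase < 0.5 else self.levels[1]
        if self.kind == "smooth_periodic":
            return self._smooth_value(t)
        if self.kind == "custom":
            return np.asarray(self.func(t), dtype=float)
        raise ValueError(f"unknown protocol kind {self.kind!r}")

    def _smooth_value(self, t: float) -> np.ndarray:
        a, b = self.levels
        half = 0.5 * self.period
        ramp = self.ramp_fraction * half
        phase = t % self.period
        # first half-period: move a -> b; second: move b -> a
        if phase < half:
            s = min(phase / ramp, 1.0)
        else:
            s = 1.0 - min((phase - half) / ramp, 1.0)
        w = 0.5 * (1.0 - np.cos(np.pi * s))  # cosine ramp, C^1 at the ends
        return (1.0 - w) * a + w * b

    # ------------------------------------------------------------------ utils
    def switches_in(self, t0: float, t1: float) -> list[float]:
        """Discontinuity times strictly inside (t0, t1)."""
        return [s for s in self.switch_times if t0 < s < t1]

    def is_continuous(self) -> bool:
        return self.kind in ("constant", "smooth_periodic") or (
            self.kind == "custom" and not self.switch_times
        )
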