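"""Unit conventions and half-life helpers.

Every decaying state variable in the model is parameterised by a half-life
(the value experimentalists report) and integrated with an exponential time
constant ``tau = half_life / ln 2``.  Times are seconds unless a parameter
is explicitly in milliseconds; hormone masses are held in picograms
internally and reported in ng or ng/mL; rates are Hz; potentials are mV.
"""

from __future__ import annotations

import math

__all__ = [
    "LN2",
    "DEFAULT_DT",
    "half_life_to_tau",
    "tau_to_half_life",
    "decay_factor",
]

LN2 = math.log(2.0)

#: Integration step in seconds (the model is defined on a 1-ms grid).
DEFAULT_DT = 0.001


def half_life_to_tau(half_life: float) -> float:
    """Convert a half-life to an exponential time constant.

    ``tau = half_life / ln 2``, in the same unit as the input.

    Raises
    ------
    ValueError
        If ``half_life`` is not strictly positive.
    """
    if not half_life > 0:
        raise ValueError(f"half-life must be > 0, got {half_life!r}")
    return half_life / LN2


def tau_to_half_life(tau: float) -> float:
    """Inverse of :func:`half_life_to_tau`."""
    if not tau > 0:
        raise ValueError(f"time constant must be > 0, got {tau!r}")
    return tau * LN2


def decay_factor(half_life: float, dt: float, mode: str = "euler") -> float:
    """Per-step multiplicative decay factor for ``dy/dt = -y / tau``.

    Parameters
    ----------
    half_life : float
        Half-life of the variable, same time unit as ``dt``.
    dt : float
        Integration step.
    mode : {"euler", "exact"}
        ``"euler"`` gives the forward-Euler factor ``1 - dt/tau`` (the
        model's native scheme); ``"exact"`` gives ``exp(-dt/tau)``.
    """
    tau = half_life_to_tau(half_life)
    if mode == "euler":
        f = 1.0 - dt / tau
        if f < 0.0:
            raise ValueError(
                f"dt={dt} too large for Euler decay with half-life {half_life}"
            )
        return f
    if mode == "exact":
        return math.exp(-dt / tau)
    raise ValueError(f"unknown decay mode {mode!r}")
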