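"""Two-compartment clearance of oxytocin from plasma.

Secreted oxytocin enters the plasma compartment, is cleared from it
(kidneys and liver) with an exponential half-life, and diffuses between
plasma and extravascular fluid down the concentration gradient.  Doses
are given per 100 g body weight as in the reference experiments and
scaled to the configured rat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels
from .params import PlasmaParams
from .units import DEFAULT_DT, half_life_to_tau

__all__ = [
    "PlasmaState",
    "ExogenousInput",
    "PlasmaResult",
    "HalfLifeResult",
    "diff_rate",
    "step_plasma",
    "run_plasma",
    "infusion_rate_pg_per_s",
    "bolus_mass_pg",
    "apparent_half_life",
]


@dataclass
class PlasmaState:
    """Oxytocin masses (pg) in plasma (x) and extravascular fluid."""

    x: float = 0.0
    x_evf: float = 0.0

    def concentration_ng_per_ml(self, params: PlasmaParams) -> float:
        return self.x / params.c_plasma / 1000.0


@dataclass(frozen=True)
class ExogenousInput:
    """Infusion or bolus of exogenous oxytocin.

    ``kind="infusion"``: ``rate_pg_per_s`` applies over
    [start, start+duration).  ``kind="bolus"``: ``total_pg`` delivered at
    a constant rate over ``duration`` (default 2 s, the reference
    injection duration).
    """

    kind: str
    start: float = 0.0
    duration: float = 1800.0
    rate_pg_per_s: float = 0.0
    total_pg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("infusion", "bolus"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.rate_pg_per_s < 0 or self.total_pg < 0:
            raise ValueError("amounts must be >= 0")

    def rate_series(self, n_steps: int, dt: float = DEFAULT_DT) -> np.ndarray:
        rate = (self.rate_pg_per_s if self.kind == "infusion"
                else self.total_pg / self.duration)
        out = np.zeros(n_steps)
        i0 = int(round(self.start / dt))
        i1 = min(int(round((self.start + self.duration) / dt)), n_steps)
        out[i0:i1] = rate
        return out


def infusion_rate_pg_per_s(ng_per_100g_per_min: float,
                           params: PlasmaParams) -> float:
    """Convert an infusion dose in ng/100 g/min to pg/s for this rat."""
    return ng_per_100g_per_min * (params.body_weight_g / 100.0) / 60.0 * 1000.0


def bolus_mass_pg(ng_per_100g: float, params: PlasmaParams) -> float:
    """Convert a bolus dose in ng/100 g to total pg for this rat."""
    return ng_per_100g * (params.body_weight_g / 100.0) * 1000.0


def diff_rate(state: PlasmaState, params: PlasmaParams) -> float:
    """Concentration gradient times mean compartment volume (pg).

    Positive when plasma concentration exceeds the extravascular one.
    """
    return (
        (state.x / params.c_plasma - state.x_evf / params.c_evf)
        * (params.c_plasma + params.c_evf) / 2.0
    )


def step_plasma(state: PlasmaState, secretion_input: float,
                exogenous: float, params: PlasmaParams,
                dt: float = DEFAULT_DT) -> PlasmaState:
    """Scalar single-step update (reference implementation), pg/s inputs."""
    if secretion_input < 0 or exogenous < 0:
        raise ValueError("inputs must be >= 0")
    d = diff_rate(state, params)
    tau_clr = half_life_to_tau(params.lambda_clr)
    tau_diff = half_life_to_tau(params.lambda_diff)
    x = state.x + dt * (secretion_input + exogenous
                        - state.x / tau_clr - d / tau_diff)
    xe = state.x_evf + dt * (d / tau_diff)
    return PlasmaState(x=max(x, 0.0), x_evf=max(xe, 0.0))


@dataclass
class PlasmaResult:
    """Per-step mass and concentration series."""

    x: np.ndarray  # pg
    x_evf: np.ndarray  # pg
    dt: float
    params: PlasmaParams

    @property
    def concentration_ng_per_ml(self) -> np.ndarray:
        return self.x / self.params.c_plasma / 1000.0

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.x.shape[0]) + 1) * self.dt

    def concentration_at(self, t: float) -> float:
        i = min(int(round(t / self.dt)) - 1, self.x.shape[0] - 1)
        return float(self.concentration_ng_per_ml[max(i, 0)])

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times[::stride],
            "x_pg": self.x[::stride],
            "x_EVF_pg": self.x_evf[::stride],
            "conc_ng_per_mL": self.concentration_ng_per_ml[::stride],
        })


def run_plasma(inputs: Union[np.ndarray, ExogenousInput,
                             Sequence[ExogenousInput], None],
               params: PlasmaParams,
               duration: float,
               secretion_series: Optional[np.ndarray] = None,
               dt: float = DEFAULT_DT,
               initial_state: Optional[PlasmaState] = None) -> PlasmaResult:
    """Integrate the two-compartment model.

    ``inputs`` may be a per-step exogenous rate array (pg/s), one or more
    :class:`ExogenousInput` protocols, or None; ``secretion_series`` is an
    optional per-step endogenous secretion rate (pg/s) added on top.
    """
    n = int(round(duration / dt))
    inflow = np.zeros(n)
    if inputs is not None:
        if isinstance(inputs, ExogenousInput):
            inputs = [inputs]
        if isinstance(inputs, np.ndarray):
            if inputs.shape[0] != n:
                raise ValueError("input series length must match step count")
            inflow += inputs
        else:
            for proto in inputs:
                inflow += proto.rate_series(n, dt)
    if secretion_series is not None:
        m = min(n, secretion_series.shape[0])
        inflow[:m] += secretion_series[:m]
    state = initial_state or PlasmaState()
    x, xe = _kernels.plasma_loop(
        inflow, dt,
        half_life_to_tau(params.lambda_clr),
        half_life_to_tau(params.lambda_diff),
        params.c_plasma, params.c_evf, state.x, state.x_evf,
    )
    return PlasmaResult(x=x, x_evf=xe, dt=dt, params=params)


@dataclass
class HalfLifeResult:
    """Apparent half-life measurement; ``reached`` is False when the
    record never falls to half the reference concentration."""

    half_life_s: float
    reached: bool
    t_ref: float
    c_ref: float


def apparent_half_life(times: np.ndarray, concentration: np.ndarray,
                       t_ref: float) -> HalfLifeResult:
    """Time for the concentration to fall to 50% of its value at t_ref.

    The crossing is linearly interpolated between samples.  If the record
    never reaches half the reference value, returns
    ``reached=False`` with ``half_life_s = nan`` (not an exception).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentration, dtype=float)
    i0 = int(np.searchsorted(times, t_ref))
    if i0 >= times.size:
        raise ValueError("t_ref beyond the end of the record")
    c_ref = conc[i0]
    if not c_ref > 0:
        raise ValueError("concentration at t_ref must be > 0")
    target = 0.5 * c_ref
    below = np.nonzero(conc[i0:] <= target)[0]
    if below.size == 0:
        return HalfLifeResult(np.nan, False, t_ref, c_ref)
    i = i0 + below[0]
    if i == i0:
        return HalfLifeResult(0.0, True, t_ref, c_ref)
    frac = (target - conc[i - 1]) / (conc[i] - conc[i - 1])
    t_cross = times[i - 1] + frac * (times[i] - times[i - 1])
    return HalfLifeResult(float(t_cross - times[i0]), True, t_ref, c_ref)
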