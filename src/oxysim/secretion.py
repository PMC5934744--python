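"""Stimulus-secretion coupling at the pituitary terminals.

Spikes invading the secretory terminals open voltage-gated calcium
channels; calcium entry is facilitated by activity-dependent spike
broadening (b) and attenuated by calcium-dependent inhibition, modelled
with fast submembrane (e) and slow cytosolic (c) calcium variables acting
through inverted Hill functions.  Secretion is proportional to e**phi and
to the releasable vesicle pool p, which refills from a large reserve pool
r.  One model terminal represents the whole gland (~9000 neurons), so
pool sizes and secretion are population-scale quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _kernels
from .params import SecretionParams
from .spiking import SpikeTrain
from .units import DEFAULT_DT, decay_factor

__all__ = [
    "TerminalState",
    "SecretionResult",
    "hill_inhibition",
    "ca_entry",
    "secretion_rate",
    "step_terminal",
    "run_secretion",
    "run_secretion_flags",
    "rest_state",
]


@dataclass
class TerminalState:
    """Full state of the terminal model (b, c, e dimensionless; pools pg)."""

    b: float = 0.0
    c: float = 0.0
    e: float = 0.0
    p: float = 5000.0
    r: float = 1e6
    s: float = 0.0  # pg/s
    cumulative_secretion: float = 0.0  # pg


def rest_state(params: SecretionParams) -> TerminalState:
    """Terminal at rest with full pools."""
    return TerminalState(p=params.p_max, r=params.r_max)


def hill_inhibition(value: float, theta: float, n: float) -> float:
    """Inverted Hill function ``1 - v**n / (v**n + theta**n)``.

    Equals 1 at ``value = 0``, 0.5 at ``value = theta`` and falls to 0 as
    ``value`` grows; used for the calcium-dependent inhibition of calcium
    entry.
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    vn = value ** n
    return 1.0 - vn / (vn + theta ** n)


def ca_entry(b: float, c: float, e: float, params: SecretionParams) -> float:
    """Spike-evoked calcium entry ``e_inhib * c_inhib * (b + b_base)``."""
    return (
        hill_inhibition(e, params.e_theta, params.e_n)
        * hill_inhibition(c, params.c_theta, params.c_n)
        * (b + params.b_base)
    )


def secretion_rate(e: float, pool: float, params: SecretionParams) -> float:
    """Secretion rate ``s = e**phi * alpha * p`` in pg/s."""
    if e < 0 or pool < 0:
        raise ValueError("e and pool must be >= 0")
    return e ** params.phi * params.alpha * pool


def step_terminal(state: TerminalState, spiked: bool,
                  params: SecretionParams, dt: float = DEFAULT_DT,
                  decay_mode: str = "euler") -> TerminalState:
    """Scalar single-step terminal update (reference implementation).

    Decays b, c, e; on a spike computes calcium entry from the
    pre-increment values and then applies the increments; updates
    secretion and the two pools with mass-conserving clipping.
    """
    dt_ms = dt * 1000.0
    b = state.b * decay_factor(params.lambda_b, dt_ms, decay_mode)
    c = state.c * decay_factor(params.lambda_c, dt_ms, decay_mode)
    e = state.e * decay_factor(params.lambda_e, dt_ms, decay_mode)
    if spiked:
        ca = ca_entry(b, c, e, params)
        b += params.k_b
        c += params.k_c * ca
        e += params.k_e * ca
    s = secretion_rate(e, state.p, params)
    release = min(s * dt, state.p)
    p = state.p - release
    r = state.r
    if p < params.p_max:
        transfer = min(params.beta * (r / params.r_max) * dt, r,
                       params.p_max - p)
        p += transfer
        r -= transfer
    return TerminalState(b=b, c=c, e=e, p=p, r=r, s=release / dt,
                         cumulative_secretion=state.cumulative_secretion
                         + release)


@dataclass
class SecretionResult:
    """Time series of the secretion rate plus the final terminal state."""

    s: np.ndarray  # pg/s per step
    dt: float
    final_state: TerminalState
    cumulative_pg: float
    burn_in: float = 0.0  # seconds of the record that are burn-in

    @property
    def cumulative_ng(self) -> float:
        return self.cumulative_pg / 1000.0

    def total_release_pg(self, t0: float = 0.0,
                         t1: Optional[float] = None) -> float:
        """Integrated release (pg) over the window [t0, t1) in seconds."""
        i0 = int(round(t0 / self.dt))
        i1 = self.s.shape[0] if t1 is None else int(round(t1 / self.dt))
        return float(self.s[i0:i1].sum() * self.dt)

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        t = (np.arange(self.s.shape[0]) + 1) * self.dt
        return pd.DataFrame({"time_s": t[::stride],
                             "s_pg_per_s": self.s[::stride]})


def run_secretion_flags(spike_flags: np.ndarray, params: SecretionParams,
                        dt: float = DEFAULT_DT,
                        initial_state: Optional[TerminalState] = None,
                        decay_mode: str = "euler") -> SecretionResult:
    """Drive the terminal with per-step spike flags (low-level entry)."""
    state = initial_state or rest_state(params)
    dt_ms = dt * 1000.0
    s, cum, b, c, e, p, r = _kernels.secretion_loop(
        spike_flags.astype(np.bool_), dt,
        params.k_b, decay_factor(params.lambda_b, dt_ms, decay_mode),
        params.b_base,
        params.k_c, decay_factor(params.lambda_c, dt_ms, decay_mode),
        params.k_e, decay_factor(params.lambda_e, dt_ms, decay_mode),
        params.c_theta, params.c_n, params.e_theta, params.e_n,
        params.beta, params.r_max, params.p_max, params.alpha, params.phi,
        state.b, state.c, state.e, state.p, state.r,
    )
    final = TerminalState(
        b=b, c=c, e=e, p=p, r=r, s=float(s[-1]) if s.size else 0.0,
        cumulative_secretion=state.cumulative_secretion + cum,
    )
    return SecretionResult(s=s, dt=dt, final_state=final, cumulative_pg=cum)


def run_secretion(train: SpikeTrain, params: SecretionParams,
                  duration: Optional[float] = None,
                  dt: float = DEFAULT_DT,
                  burn_in: float = 0.0,
                  burn_in_train: Optional[SpikeTrain] = None,
                  initial_state: Optional[TerminalState] = None,
                  decay_mode: str = "euler") -> SecretionResult:
    """Run the secretion model on a spike train.

    Parameters
    ----------
    train : SpikeTrain
        Input spikes (e.g. from the spiking model, a file, or a regular
        in-vitro pulse protocol).
    duration : float, optional
        Simulated length in seconds, defaults to ``train.duration``
        (extend it to capture post-train tail secretion).
    burn_in : float
        Seconds prepended before the train, driven by ``burn_in_train``
        (tiled if shorter) or left at rest.  The returned series covers
        burn-in plus run; ``result.burn_in`` marks the boundary and
        ``cumulative_pg`` counts the post-burn-in window only.
    initial_state : TerminalState, optional
        Starting state; default rest with full pools.
    """
    if duration is None:
        duration = train.duration
    n_run = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))
    flags = np.zeros(n_burn + n_run, np.bool_)
    if n_burn and burn_in_train is not None:
        one = burn_in_train.to_step_flags(
            int(round(burn_in_train.duration / dt)), dt)
        if one.size == 0:
            raise ValueError("burn_in_train has no steps")
        reps = int(np.ceil(n_burn / one.size))
        flags[:n_burn] = np.tile(one, reps)[:n_burn]
    flags[n_burn:] = train.to_step_flags(n_run, dt)

    res = run_secretion_flags(flags, params, dt, initial_state, decay_mode)
    res.burn_in = n_burn * dt
    res.cumulative_pg = res.total_release_pg(t0=res.burn_in)
    return res
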