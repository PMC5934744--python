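"""Modified leaky integrate-and-fire model of an oxytocin neuron.

The neuron receives excitatory and inhibitory postsynaptic potentials
(PSPs, fixed +-2 mV) arriving Poisson-randomly.  The synaptic potential
V_syn decays with a 3.5-ms half-life; when V = V_rest + V_syn - HAP - AHP
crosses threshold a spike is emitted and two post-spike hyperpolarisations
are incremented: the large, fast HAP (refractoriness over tens of ms) and
the small, slow AHP (activity-dependent negative feedback over seconds).
A CCK injection is modelled as a transient extra EPSP rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _kernels
from .params import CCKParams, SpikingParams
from .units import DEFAULT_DT, decay_factor, half_life_to_tau

__all__ = [
    "SpikeTrain",
    "NeuronState",
    "SpikingResult",
    "sample_psp_counts",
    "psp_event_times",
    "step_cck_drive",
    "cck_drive_series",
    "step_membrane",
    "run_spiking",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds over ``[0, duration]``."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return len(self) / self.duration if self.duration > 0 else np.nan

    @classmethod
    def regular(cls, frequency: float, n_pulses: int,
                start: float = 0.0, duration: Optional[float] = None
                ) -> "SpikeTrain":
        """Regular train of ``n_pulses`` at ``frequency`` Hz."""
        if frequency <= 0:
            raise ValueError("frequency must be > 0")
        times = start + np.arange(n_pulses) / frequency
        if duration is None:
            duration = float(times[-1]) if n_pulses else start
        return cls(times=times, duration=duration)

    def to_step_flags(self, n_steps: int, dt: float = DEFAULT_DT) -> np.ndarray:
        """Boolean per-step spike flags on the integration grid."""
        flags = np.zeros(n_steps, np.bool_)
        idx = np.round(self.times / dt).astype(np.int64)
        flags[idx[idx < n_steps]] = True
        return flags

    @classmethod
    def from_step_flags(cls, flags: np.ndarray, dt: float = DEFAULT_DT
                        ) -> "SpikeTrain":
        idx = np.nonzero(flags)[0]
        return cls(times=idx * dt, duration=flags.shape[0] * dt)

    def shifted(self, offset: float) -> "SpikeTrain":
        return SpikeTrain(times=self.times + offset,
                          duration=self.duration + offset)


@dataclass
class NeuronState:
    """Instantaneous state for the scalar (single-step) membrane update."""

    t: float = 0.0
    v: float = -56.0
    v_syn: float = 0.0
    hap: float = 0.0
    ahp: float = 0.0
    i_rcck: float = 0.0


def sample_psp_counts(rate: float, dt: float, rng: np.random.Generator,
                      size: Optional[int] = None
                      ) -> Union[int, np.ndarray]:
    """Poisson PSP counts per step with mean ``rate * dt``.

    At 1-ms resolution this per-step count formulation is statistically
    equivalent to drawing exponential arrival gaps (see
    :func:`psp_event_times`).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = rng.poisson(rate * dt, size)
    return out


def psp_event_times(rate: float, duration: float,
                    rng: np.random.Generator) -> np.ndarray:
    """PSP arrival times from exponential gaps ``-log(1 - u) / rate``.

    The event-time formulation of the Poisson input process; provided for
    cross-validation of the per-step count sampler.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return np.empty(0)
    # draw in blocks until past `duration`
    out = []
    t = 0.0
    block = max(16, int(rate * duration * 1.2) + 16)
    while t < duration:
        gaps = -np.log1p(-rng.random(block)) / rate
        arr = t + np.cumsum(gaps)
        out.append(arr)
        t = arr[-1]
    times = np.concatenate(out)
    return times[times < duration]


def step_cck_drive(i_rcck: float, t: float, cck: CCKParams,
                   dt: float = DEFAULT_DT) -> float:
    """One Euler step of the CCK-evoked extra EPSP rate (Hz).

    During the injection window the ramp ``k / duration`` is applied
    (``k`` = ``cck.drive_amplitude``); the rate always decays with the
    CCK plasma half-life.
    """
    if i_rcck < 0:
        raise ValueError("i_rcck must be >= 0")
    tau = half_life_to_tau(cck.half_life)
    in_window = cck.start <= t < cck.start + cck.duration
    ramp = cck.drive_amplitude / cck.duration if in_window else 0.0
    out = i_rcck + dt * (ramp - i_rcck / tau)
    return max(out, 0.0)


def cck_drive_series(cck: CCKParams, n_steps: int,
                     dt: float = DEFAULT_DT) -> np.ndarray:
    """Euler-integrated I_rCCK (Hz) on the full step grid."""
    return _kernels.cck_drive_loop(
        n_steps, dt, cck.drive_amplitude / cck.duration, cck.start,
        cck.duration, half_life_to_tau(cck.half_life),
    )


def step_membrane(state: NeuronState, epsp_n: int, ipsp_n: int,
                  p: SpikingParams, dt: float = DEFAULT_DT,
                  decay_mode: str = "euler") -> tuple[NeuronState, bool]:
    """Scalar single-step membrane update (reference implementation).

    Mirrors the compiled loop: decay, add input, threshold, post-spike
    increments effective from the next step.
    """
    if epsp_n < 0 or ipsp_n < 0:
        raise ValueError("PSP counts must be >= 0")
    dt_ms = dt * 1000.0
    v_syn = state.v_syn * decay_factor(p.lambda_syn, dt_ms, decay_mode)
    hap = state.hap * decay_factor(p.lambda_hap, dt_ms, decay_mode)
    ahp = state.ahp * decay_factor(p.lambda_ahp, dt_ms, decay_mode)
    v_syn += p.epsp_h * epsp_n + p.ipsp_h * ipsp_n
    v = p.v_rest + v_syn - hap - ahp
    spiked = v > p.v_thresh
    if spiked:
        hap += p.k_hap
        ahp += p.k_ahp
    return (
        NeuronState(t=state.t + dt, v=v, v_syn=v_syn, hap=hap, ahp=ahp,
                    i_rcck=state.i_rcck),
        spiked,
    )


@dataclass
class SpikingResult:
    """Output of :func:`run_spiking`."""

    train: SpikeTrain
    spike_flags: np.ndarray
    dt: float
    traces: Optional[pd.DataFrame] = None

    @property
    def mean_rate(self) -> float:
        return self.train.mean_rate


def run_spiking(params: SpikingParams,
                cck: Optional[CCKParams] = None,
                duration: float = 1000.0,
                seed: Union[int, np.random.Generator, None] = 0,
                dt: float = DEFAULT_DT,
                decay_mode: str = "euler",
                record_traces: bool = False,
                epsp_rate_series: Optional[np.ndarray] = None
                ) -> SpikingResult:
    """Simulate the spiking model.

    Parameters
    ----------
    params : SpikingParams
    cck : CCKParams, optional
        If given, the CCK-evoked extra EPSP rate is added to ``i_re``.
    duration : float
        Run length in seconds.
    seed : int or Generator
        Source of randomness for PSP arrivals; identical seeds give
        identical runs.
    epsp_rate_series : ndarray, optional
        Per-step total EPSP rate (Hz) overriding ``i_re`` (+ CCK drive);
        used by schedule-driven protocols.  The IPSP rate stays
        ``params.i_ri`` throughout.
    record_traces : bool
        Record V, V_syn, HAP, AHP and I_rCCK per step (memory ~40 B/step).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    i_rcck = None
    if epsp_rate_series is not None:
        rate_e = np.asarray(epsp_rate_series, dtype=float)
        if rate_e.shape[0] != n:
            raise ValueError("epsp_rate_series length must match step count")
    elif cck is not None and cck.dose > 0:
        i_rcck = cck_drive_series(cck, n, dt)
        rate_e = params.i_re + i_rcck
    else:
        rate_e = np.full(n, params.i_re)

    epsp_n = rng.poisson(rate_e * dt)
    ipsp_n = rng.poisson(params.i_ri * dt, n)
    syn_input = params.epsp_h * epsp_n + params.ipsp_h * ipsp_n

    dt_ms = dt * 1000.0
    args = (
        syn_input.astype(np.float64), dt,
        decay_factor(params.lambda_syn, dt_ms, decay_mode),
        decay_factor(params.lambda_hap, dt_ms, decay_mode),
        decay_factor(params.lambda_ahp, dt_ms, decay_mode),
        params.k_hap, params.k_ahp, params.v_rest, params.v_thresh,
    )
    traces = None
    if record_traces:
        flags, v, vs, hap, ahp = _kernels.membrane_loop_traces(*args)
        traces = pd.DataFrame({
            "time_s": (np.arange(n) + 1) * dt,
            "V_mV": v,
            "V_syn_mV": vs,
            "HAP_mV": hap,
            "AHP_mV": ahp,
            "I_rCCK_Hz": i_rcck if i_rcck is not None else np.zeros(n),
        })
    else:
        flags = _kernels.membrane_loop(*args)

    train = SpikeTrain.from_step_flags(flags, dt)
    # from_step_flags sets duration = n*dt which equals `duration`
    return SpikingResult(train=train, spike_flags=flags, dt=dt, traces=traces)
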