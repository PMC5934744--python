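"""Composite experiment protocols.

Orchestrates the model chain through the protocols used to characterise
it: CCK injections through spiking, secretion and plasma; in-vitro
fixed-frequency pulse trains; PSP-rate calibration to a target firing
rate; the signal-detection assay probing how reliably a +1 spikes/s
challenge shows up in secretion; and heterogeneous populations of model
neurons with log-normally distributed input rates and CCK sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import CCKParams, SecretionParams, SpikingParams
from .plasma import PlasmaParams, PlasmaResult, run_plasma
from .secretion import rest_state, run_secretion_flags
from .spiking import SpikeTrain, cck_drive_series, run_spiking
from .stats import binned_rate, coefficient_of_variation
from .units import DEFAULT_DT

__all__ = [
    "CCKExperiment",
    "CCKExperimentResult",
    "simulate_cck_experiment",
    "CalibrationError",
    "CalibrationResult",
    "calibrate_basal_rate",
    "calibrate_epsp_increment",
    "PulseTrainProtocol",
    "PulseProtocolResult",
    "run_pulse_protocol",
    "DetectionAssay",
    "run_detection_assay",
    "PopulationSpec",
    "sample_population",
    "load_population_table",
    "simulate_population",
    "PopulationResult",
]


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-run generator derived from a master seed."""
    return np.random.default_rng([int(master_seed)] + [int(k) for k in key])


# ---------------------------------------------------------------------------
# CCK injection through the full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCKExperiment:
    """A repeated CCK-injection run.

    ``basal_window`` seconds before the injection define the basal rate;
    the response is summarised both as the 5-minute post-injection mean
    increment (``post_window``) and as the mean over
    ``post_peak_window`` seconds following the peak of the averaged
    response.  ``cv_pre``/``cv_post`` delimit the variability window
    (50 s before plus 300 s after injection).
    """

    dose: float = 20.0  # µg/kg
    basal_rate_hz: float = 292.0  # I_re = I_ri, Hz
    n_runs: int = 23
    master_seed: int = 0
    cck_start: float = 300.0
    duration: Optional[float] = None  # default cck_start + post_window
    basal_window: float = 240.0
    post_window: float = 300.0
    post_peak_window: float = 25.0
    cv_pre: float = 50.0
    cv_post: float = 300.0
    with_ahp: bool = True

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class CCKExperimentResult:
    """Per-run 1-s binned series and response summaries."""

    rate_bins: np.ndarray  # (n_runs, n_bins) spikes/s
    secretion_bins: Optional[np.ndarray]  # (n_runs, n_bins) pg/s
    plasma_conc: Optional[np.ndarray]  # (n_runs, n_bins) ng/mL
    experiment: CCKExperiment
    summary: dict

    @property
    def mean_rate_series(self) -> np.ndarray:
        return self.rate_bins.mean(axis=0)


def simulate_cck_experiment(
    exp: CCKExperiment,
    spiking_params: Optional[SpikingParams] = None,
    cck_params: Optional[CCKParams] = None,
    secretion_params: Optional[SecretionParams] = None,
    plasma_params: Optional[PlasmaParams] = None,
    dt: float = DEFAULT_DT,
) -> CCKExperimentResult:
    """Run ``exp.n_runs`` seeded repetitions of a CCK injection.

    Always chains spiking; adds the secretion stage when
    ``secretion_params`` is given and the plasma stage when additionally
    ``plasma_params`` is given.
    """
    sp = spiking_params or SpikingParams()
    sp = sp.replace(i_re=exp.basal_rate_hz, i_ri=exp.basal_rate_hz,
                    k_ahp=sp.k_ahp if exp.with_ahp else 0.0)
    cck = (cck_params or CCKParams()).replace(dose=exp.dose,
                                              start=exp.cck_start)
    duration = exp.duration or exp.cck_start + exp.post_window
    n_bins = int(duration)

    rate_bins = np.empty((exp.n_runs, n_bins))
    secr_bins = (np.empty((exp.n_runs, n_bins))
                 if secretion_params is not None else None)
    conc_bins = (np.empty((exp.n_runs, n_bins))
                 if secretion_params is not None and plasma_params is not None
                 else None)

    for i in range(exp.n_runs):
        res = run_spiking(sp, cck=cck, duration=duration,
                          seed=_rng(exp.master_seed, i), dt=dt)
        rate_bins[i] = binned_rate(res.train, 1.0, 0.0, n_bins)
        if secr_bins is not None:
            sres = run_secretion_flags(res.spike_flags, secretion_params, dt)
            per_step = sres.s[: n_bins * int(round(1.0 / dt))]
            secr_bins[i] = per_step.reshape(n_bins, -1).mean(axis=1)
            if conc_bins is not None:
                pres = run_plasma(None, plasma_params, duration,
                                  secretion_series=sres.s, dt=dt)
                conc = pres.concentration_ng_per_ml[
                    : n_bins * int(round(1.0 / dt))]
                conc_bins[i] = conc.reshape(n_bins, -1).mean(axis=1)

    t0 = int(exp.cck_start)
    b0 = int(exp.cck_start - exp.basal_window)
    basal = rate_bins[:, b0:t0].mean(axis=1)
    post5 = rate_bins[:, t0:t0 + int(exp.post_window)].mean(axis=1)

    mean_series = rate_bins.mean(axis=0)
    # peak of the averaged response, lightly smoothed over 5 s
    post = mean_series[t0:]
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(post, kernel, mode="same")
    peak_bin = t0 + int(np.argmax(smooth))
    w = int(exp.post_peak_window)
    inc_post_peak = (mean_series[peak_bin:peak_bin + w].mean()
                     - basal.mean())

    cv0 = int(exp.cck_start - exp.cv_pre)
    cv1 = int(exp.cck_start + exp.cv_post)

    def second_by_second_cv(bins: np.ndarray) -> float:
        # CV across runs at each 1-s bin, averaged over the window: the
        # "second-by-second" variability of the ensemble
        w = bins[:, cv0:cv1]
        return float((w.std(axis=0) / w.mean(axis=0)).mean())

    summary = {
        "basal_rate": float(basal.mean()),
        "increment_5min": float((post5 - basal).mean()),
        "increment_post_peak": float(inc_post_peak),
        "peak_time_s": float(peak_bin),
        "rate_cv": second_by_second_cv(rate_bins),
        "rate_cv_per_run": float(np.mean(
            [coefficient_of_variation(r[cv0:cv1]) for r in rate_bins])),
    }
    if secr_bins is not None:
        summary["basal_secretion_pg_per_s"] = float(
            secr_bins[:, b0:t0].mean())
        summary["secretion_cv"] = second_by_second_cv(secr_bins)
        summary["secretion_cv_per_run"] = float(np.mean(
            [coefficient_of_variation(s[cv0:cv1]) for s in secr_bins]))
    return CCKExperimentResult(rate_bins, secr_bins, conc_bins, exp, summary)


# ---------------------------------------------------------------------------
# PSP-rate calibration
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    """Raised when the target firing rate is outside the search bracket."""


@dataclass
class CalibrationResult:
    rate_hz: float
    achieved_rate: float
    n_evaluations: int


def _mean_rate(params: SpikingParams, duration: float, n_seeds: int,
               master_seed: int, dt: float) -> float:
    total = 0.0
    for s in range(n_seeds):
        res = run_spiking(params, duration=duration,
                          seed=_rng(master_seed, 77, s), dt=dt)
        total += res.mean_rate
    return total / n_seeds


def calibrate_basal_rate(
    target_rate: float,
    params: Optional[SpikingParams] = None,
    tolerance: float = 0.05,
    bracket: tuple[float, float] = (0.0, 2000.0),
    run_duration: float = 500.0,
    n_seeds: int = 5,
    master_seed: int = 0,
    max_iter: int = 20,
    dt: float = DEFAULT_DT,
) -> CalibrationResult:
    """Find the balanced PSP rate (I_re = I_ri) giving ``target_rate``.

    Bisection on the input rate using averaged seeded runs (the same
    seeds at every evaluation, so the objective is monotone).  A target
    of 0 returns rate 0.  Raises :class:`CalibrationError` with the
    bracket values when the target is unreachable.
    """
    if target_rate < 0:
        raise ValueError("target rate must be >= 0")
    base = params or SpikingParams()
    if target_rate == 0:
        return CalibrationResult(0.0, 0.0, 0)

    def f(rate: float) -> float:
        return _mean_rate(base.replace(i_re=rate, i_ri=rate),
                          run_duration, n_seeds, master_seed, dt)

    lo, hi = bracket
    f_hi = f(hi)
    n_eval = 1
    if f_hi < target_rate:
        raise CalibrationError(
            f"target {target_rate} spikes/s unreachable: rate({hi} Hz) = "
            f"{f_hi:.3f} spikes/s")
    mid, v = hi, f_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        n_eval += 1
        if abs(v - target_rate) < tolerance:
            break
        if v < target_rate:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(mid, v, n_eval)


def calibrate_epsp_increment(
    basal_rate_hz: float,
    target_rate: float,
    params: Optional[SpikingParams] = None,
    tolerance: float = 0.05,
    bracket: tuple[float, float] = (0.0, 500.0),
    run_duration: float = 500.0,
    n_seeds: int = 5,
    master_seed: int = 0,
    max_iter: int = 20,
    dt: float = DEFAULT_DT,
) -> CalibrationResult:
    """EPSP-rate increment (IPSP rate fixed) raising the firing rate to
    ``target_rate`` from the basal configuration ``i_re = i_ri =
    basal_rate_hz``."""
    base = (params or SpikingParams()).replace(i_re=basal_rate_hz,
                                               i_ri=basal_rate_hz)

    def f(d: float) -> float:
        return _mean_rate(base.replace(i_re=basal_rate_hz + d),
                          run_duration, n_seeds, master_seed, dt)

    lo, hi = bracket
    f_hi = f(hi)
    n_eval = 1
    if f_hi < target_rate:
        raise CalibrationError(
            f"target {target_rate} spikes/s unreachable: "
            f"rate(+{hi} Hz) = {f_hi:.3f} spikes/s")
    mid, v = hi, f_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        n_eval += 1
        if abs(v - target_rate) < tolerance:
            break
        if v < target_rate:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(mid, v, n_eval)


# ---------------------------------------------------------------------------
# In-vitro pulse-train protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainProtocol:
    """Fixed-frequency electrical stimulation of the isolated gland.

    ``normalize=True`` reports secretion as an S2/S1 ratio against a
    reference 600-pulse train at 12 Hz applied to the same terminal
    ``rest_interval`` seconds earlier.
    """

    frequency: float
    n_pulses: int
    tail: float = 1.0  # post-train secretion window, s
    normalize: bool = False
    reference_frequency: float = 12.0
    reference_pulses: int = 600
    rest_interval: float = 600.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")


@dataclass
class PulseProtocolResult:
    total_pg: float
    per_pulse_pg: float
    s2_over_s1: Optional[float]
    result: Optional[SecretionResult] = None


def _train_release(train_times: np.ndarray, duration: float,
                   params: SecretionParams, state, tail: float,
                   dt: float) -> tuple[float, object]:
    n = int(round((duration + tail) / dt))
    flags = np.zeros(n, np.bool_)
    idx = np.round(train_times / dt).astype(np.int64)
    flags[idx[idx < n]] = True
    res = run_secretion_flags(flags, params, dt, initial_state=state)
    return res.cumulative_pg, res.final_state


def run_pulse_protocol(proto: PulseTrainProtocol,
                       params: Optional[SecretionParams] = None,
                       dt: float = DEFAULT_DT) -> PulseProtocolResult:
    """Drive the secretion model with a regular pulse train from rest
    with full pools; secretion is integrated over the train plus
    ``proto.tail`` seconds."""
    params = params or SecretionParams()
    if proto.n_pulses == 0:
        return PulseProtocolResult(0.0, 0.0,
                                   None if not proto.normalize else np.nan)
    times = np.arange(proto.n_pulses) / proto.frequency
    train_dur = proto.n_pulses / proto.frequency

    s2_over_s1 = None
    if proto.normalize:
        ref_times = np.arange(proto.reference_pulses) / proto.reference_frequency
        ref_dur = proto.reference_pulses / proto.reference_frequency
        s1, state = _train_release(ref_times, ref_dur, params,
                                   rest_state(params), proto.tail, dt)
        # rest between S1 and S2 (no spikes, pools recover)
        n_rest = int(round(proto.rest_interval / dt))
        rest = run_secretion_flags(np.zeros(n_rest, np.bool_), params, dt,
                                   initial_state=state)
        s2, _ = _train_release(times, train_dur, params,
                               rest.final_state, proto.tail, dt)
        total = s2
        s2_over_s1 = s2 / s1 if s1 > 0 else np.nan
    else:
        n = int(round((train_dur + proto.tail) / dt))
        flags = np.zeros(n, np.bool_)
        idx = np.round(times / dt).astype(np.int64)
        flags[idx[idx < n]] = True
        res = run_secretion_flags(flags, params, dt,
                                  initial_state=rest_state(params))
        total = res.cumulative_pg
        return PulseProtocolResult(total, total / proto.n_pulses, None, res)

    return PulseProtocolResult(total, total / proto.n_pulses, s2_over_s1)


# ---------------------------------------------------------------------------
# Signal-detection assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionAssay:
    """Alternating basal/challenge EPSP-rate schedule.

    Episodes of equal duration alternate between the basal EPSP rate
    (calibrated to ``basal_rate_sps``) and a challenge rate (basal EPSP
    rate plus an increment calibrated to raise the mean firing rate by
    ``increment_sps``).  A challenge episode whose total secretion does
    not exceed the immediately preceding basal episode's counts as a
    detection error (ties are errors).
    """

    basal_rate_sps: float = 3.0
    increment_sps: float = 1.0
    episode_durations: Sequence[float] = (1.0,)
    total_duration: float = 6000.0
    burn_in: float = 200.0
    n_runs: int = 5
    master_seed: int = 0
    with_ahp: bool = True

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.episode_durations):
            raise ValueError("episode durations must be > 0")


def detection_error_pct(basal_totals: np.ndarray,
                        challenge_totals: np.ndarray) -> float:
    """Percentage of challenge episodes whose secretion does not exceed
    the preceding basal episode's (ties count as errors)."""
    basal_totals = np.asarray(basal_totals, dtype=float)
    challenge_totals = np.asarray(challenge_totals, dtype=float)
    if basal_totals.shape != challenge_totals.shape or basal_totals.size == 0:
        raise ValueError("need equal, non-empty episode arrays")
    return float(np.mean(challenge_totals <= basal_totals) * 100.0)


def run_detection_assay(assay: DetectionAssay,
                        spiking_params: Optional[SpikingParams] = None,
                        secretion_params: Optional[SecretionParams] = None,
                        dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Run the detection assay; returns one row per (episode duration,
    run) with the error percentage, plus calibrated rates as attrs.

    The per-run percentage pools all challenge episodes of that run;
    averaging the per-run values gives the headline error rate.
    """
    sp = spiking_params or SpikingParams()
    if not assay.with_ahp:
        sp = sp.replace(k_ahp=0.0)
    secp = secretion_params or SecretionParams()

    cal_b = calibrate_basal_rate(assay.basal_rate_sps, sp,
                                 master_seed=assay.master_seed)
    base_rate = cal_b.rate_hz
    sp = sp.replace(i_re=base_rate, i_ri=base_rate)
    cal_d = calibrate_epsp_increment(
        base_rate, assay.basal_rate_sps + assay.increment_sps, sp,
        master_seed=assay.master_seed)
    delta = cal_d.rate_hz

    rows = []
    n_burn = int(round(assay.burn_in / dt))
    for ep_dur in assay.episode_durations:
        eps = int(round(ep_dur / dt))
        n_pairs = int(assay.total_duration / (2 * ep_dur))
        n_sched = 2 * n_pairs * eps
        rate = np.full(n_burn + n_sched, base_rate)
        sched = rate[n_burn:].reshape(2 * n_pairs, eps)
        sched[1::2] += delta  # challenge episodes
        for run in range(assay.n_runs):
            res = run_spiking(sp, duration=(n_burn + n_sched) * dt,
                              seed=_rng(assay.master_seed, 5, run),
                              epsp_rate_series=rate, dt=dt)
            sres = run_secretion_flags(res.spike_flags, secp, dt)
            per_ep = sres.s[n_burn:].reshape(2 * n_pairs, eps).sum(axis=1) * dt
            errors = detection_error_pct(per_ep[0::2], per_ep[1::2])
            rows.append({"episode_duration_s": ep_dur, "run": run,
                         "error_pct": errors,
                         "with_ahp": assay.with_ahp})
    out = pd.DataFrame(rows)
    out.attrs["basal_epsp_rate_hz"] = base_rate
    out.attrs["challenge_increment_hz"] = delta
    return out


# ---------------------------------------------------------------------------
# Heterogeneous populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Log-normally heterogeneous population of model neurons.

    ``rate_mean``/``rate_sd`` parameterise the arithmetic mean and SD of
    the balanced PSP rate; ``cck_mean``/``cck_sd`` those of the CCK dose
    sensitivity.  An SD of 0 yields identical neurons.
    """

    n_neurons: int = 23
    rate_mean: float = 292.0
    rate_sd: float = 292.0
    cck_mean: float = 20.0
    cck_sd: float = 20.0
    with_ahp: bool = True

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.rate_mean <= 0 or self.cck_mean < 0:
            raise ValueError("means must be positive")


def _lognormal(mean: float, sd: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Log-normal samples with the given arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_population(spec: PopulationSpec, master_seed: int = 0
                      ) -> pd.DataFrame:
    """Sample per-neuron (PSP rate, CCK sensitivity) values."""
    rng = _rng(master_seed, 11)
    rates = _lognormal(spec.rate_mean, spec.rate_sd, spec.n_neurons, rng)
    doses = _lognormal(spec.cck_mean, spec.cck_sd, spec.n_neurons, rng) \
        if spec.cck_mean > 0 else np.zeros(spec.n_neurons)
    return pd.DataFrame({
        "neuron": np.arange(1, spec.n_neurons + 1),
        "I_re_Hz": rates,
        "k_CCK": doses,
        "ahp": spec.with_ahp,
    })


#: Scenario names available in the shipped population table.
POPULATION_SCENARIOS = (
    "ahp_fixed",
    "ahp_random_rate",
    "ahp_random_rate_cck",
    "noahp_fixed",
    "noahp_random_rate_cck",
)


def load_population_table(scenario: str = "ahp_random_rate_cck"
                          ) -> pd.DataFrame:
    """Load the 23-neuron parameter table shipped with the package.

    Columns ``neuron, I_re_Hz, k_CCK, ahp``; ``scenario`` selects one of
    the five published columns (with/without AHP, fixed or randomised
    input rate and CCK sensitivity).
    """
    if scenario not in POPULATION_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {POPULATION_SCENARIOS}")
    path = resources.files("oxysim") / "data" / "population_params.csv"
    with resources.as_file(path) as p:
        table = pd.read_csv(p)
    out = table[table["scenario"] == scenario].drop(columns=["scenario"])
    return out.reset_index(drop=True)


@dataclass
class PopulationResult:
    """Across-neuron per-1-s-bin aggregates of a population run."""

    rate_mean: np.ndarray
    rate_sd: np.ndarray
    secretion_mean: Optional[np.ndarray]
    secretion_sd: Optional[np.ndarray]
    summary: dict


def simulate_population(
    population: pd.DataFrame,
    cck: Optional[CCKParams] = None,
    spiking_params: Optional[SpikingParams] = None,
    secretion_params: Optional[SecretionParams] = None,
    duration: float = 600.0,
    master_seed: int = 0,
    dt: float = DEFAULT_DT,
) -> PopulationResult:
    """Run each neuron of ``population`` independently and aggregate.

    Each row supplies the balanced PSP rate (``I_re_Hz``), the per-neuron
    CCK dose (``k_CCK``, µg/kg) and the AHP flag.  PSP noise is
    independent across neurons.  With a single neuron the across-neuron
    SD is zero by construction (only temporal noise remains).
    """
    sp0 = spiking_params or SpikingParams()
    cck0 = cck or CCKParams(start=300.0)
    n_bins = int(duration)
    rates = np.empty((len(population), n_bins))
    secr = (np.empty((len(population), n_bins))
            if secretion_params is not None else None)
    for i, row in population.reset_index(drop=True).iterrows():
        sp = sp0.replace(i_re=float(row["I_re_Hz"]),
                         i_ri=float(row["I_re_Hz"]),
                         k_ahp=sp0.k_ahp if bool(row["ahp"]) else 0.0)
        this_cck = cck0.replace(dose=float(row["k_CCK"]))
        res = run_spiking(sp, cck=this_cck, duration=duration,
                          seed=_rng(master_seed, 23, i), dt=dt)
        rates[i] = binned_rate(res.train, 1.0, 0.0, n_bins)
        if secr is not None:
            sres = run_secretion_flags(res.spike_flags, secretion_params, dt)
            secr[i] = sres.s[: n_bins * int(round(1.0 / dt))] \
                .reshape(n_bins, -1).mean(axis=1)

    t0 = min(int(cck0.start), n_bins)
    basal_sl = slice(max(t0 - 240, 0), t0)
    post_sl = slice(t0, min(t0 + 300, n_bins))
    has_post = post_sl.stop > post_sl.start
    rate_sd = rates.std(axis=0)
    summary = {
        "basal_rate_mean": float(rates[:, basal_sl].mean()),
        "basal_rate_sd": float(rate_sd[basal_sl].mean()),
        "post_cck_rate_sd": float(rate_sd[post_sl].mean())
        if has_post else np.nan,
        "increment_5min": float(rates[:, post_sl].mean()
                                - rates[:, basal_sl].mean())
        if has_post else np.nan,
    }
    sec_mean = sec_sd = None
    if secr is not None:
        sec_mean = secr.mean(axis=0)
        sec_sd = secr.std(axis=0)
        summary["basal_secretion_mean"] = float(secr[:, basal_sl].mean())
        summary["basal_secretion_sd"] = float(sec_sd[basal_sl].mean())
    return PopulationResult(rates.mean(axis=0), rate_sd, sec_mean, sec_sd,
                            summary)
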