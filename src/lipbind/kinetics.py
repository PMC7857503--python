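"""Stopped-flow kinetic analysis.

Association traces follow a single rising exponential

    F(t) = dF_max * (1 - exp(-k_obs * t)) + C

and dissociation traces (after rapid mixing with unlabeled acceptor
liposomes) follow a single or double falling exponential

    F(t) = dF1 * exp(-k1 * t) [+ dF2 * exp(-k2 * t)] + C.

Points earlier than the instrument dead time (default 1.4 ms) are excluded
from all fits. The mole-fraction association rate constant is

    k_on,x = (k_obs - k_off) * [H2O] / [L]

with [L] the accessible lipid concentration after mixing (equal-volume
mixing halves the syringe concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import lmfit
import numpy as np

from .constants import DEFAULT_DEAD_TIME_S
from .errors import (
    AlignmentError,
    DegenerateAmplitudeError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    NonPositiveRateError,
)
from .titration import PartitioningInputs

__all__ = [
    "KineticTrace",
    "AssociationFit",
    "DissociationFit",
    "RateResult",
    "average_replicate_traces",
    "fit_association",
    "fit_dissociation",
    "association_rate_constant",
    "normalize_trace",
]


@dataclass(frozen=True)
class KineticTrace:
    """A stopped-flow time series with dead-time and replicate provenance."""

    time: np.ndarray  # seconds, strictly ascending
    signal: np.ndarray
    dead_time: float = DEFAULT_DEAD_TIME_S
    n_replicates_averaged: int = 1

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise InvalidArgumentError("time and signal must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("time must be strictly ascending")
        if self.dead_time < 0:
            raise InvalidArgumentError("dead_time must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)

    def analysis_window(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, F) restricted to t >= dead_time."""
        keep = self.time >= self.dead_time
        return self.time[keep], self.signal[keep]

    def with_signal(self, values) -> "KineticTrace":
        return replace(self, signal=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class AssociationFit:
    """Single-exponential association parameters."""

    k_obs: float  # 1/s
    delta_f_max: float
    offset_c: float
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k_obs <= 0:
            raise InvalidArgumentError("k_obs must be > 0")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.delta_f_max * (1.0 - np.exp(-self.k_obs * t)) + self.offset_c

    @property
    def total_amplitude(self) -> float:
        return self.delta_f_max


@dataclass(frozen=True)
class DissociationFit:
    """Single or double-exponential dissociation parameters.

    Rates are stored fast-first; ``amplitude_fractions`` are percentages of
    the total amplitude, matching the usual reporting convention.
    """

    model: str  # "single" or "double"
    rates: tuple[float, ...]
    amplitudes: tuple[float, ...]
    offset_c: float
    stderr: dict = field(default_factory=dict)
    information_criterion: dict = field(default_factory=dict)  # AICc per model

    def __post_init__(self):
        if self.model not in ("single", "double"):
            raise InvalidArgumentError("model must be 'single' or 'double'")
        if any(r <= 0 for r in self.rates):
            raise InvalidArgumentError("all rates must be > 0")
        if len(self.rates) != len(self.amplitudes):
            raise InvalidArgumentError("rates/amplitudes length mismatch")
        if self.model == "double" and not self.rates[0] > self.rates[1]:
            raise InvalidArgumentError("double-exponential rates must be fast-first")

    @property
    def amplitude_fractions(self) -> tuple[float, ...]:
        total = sum(self.amplitudes)
        if total == 0:
            raise DegenerateAmplitudeError("zero total amplitude")
        return tuple(100.0 * a / total for a in self.amplitudes)

    @property
    def total_amplitude(self) -> float:
        return float(sum(self.amplitudes))

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset_c, dtype=float)
        for a, k in zip(self.amplitudes, self.rates):
            out += a * np.exp(-k * t)
        return out


@dataclass(frozen=True)
class RateResult:
    """Mole-fraction association rate constant and its inputs."""

    kon_x: float  # 1/s, mole-fraction convention
    k_obs: float
    k_off: float
    water_molarity: float
    accessible_lipid: float

    def __post_init__(self):
        if self.kon_x <= 0:
            raise InvalidArgumentError("kon_x must be > 0")


def average_replicate_traces(traces: Sequence[KineticTrace]) -> KineticTrace:
    """Pointwise mean of replicate shots sharing a common time base.

    Dead time of the average is the maximum over the inputs (the most
    conservative exclusion window).
    """
    if len(traces) < 2:
        raise InsufficientDataError("need >= 2 replicate traces to average")
    base = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != base.shape or np.any(np.abs(tr.time - base) > 1e-9):
            raise AlignmentError("replicate traces do not share a time base")
    mean = np.mean([tr.signal for tr in traces], axis=0)
    return KineticTrace(
        time=base.copy(),
        signal=mean,
        dead_time=max(tr.dead_time for tr in traces),
        n_replicates_averaged=sum(tr.n_replicates_averaged for tr in traces),
    )


def fit_association(trace: KineticTrace) -> AssociationFit:
    """Fit F = dF_max*(1 - exp(-k_obs t)) + C on t >= dead_time."""
    t, y = trace.analysis_window()
    if t.size < 4:
        raise InsufficientDataError("need >= 4 points beyond the dead time")

    span = float(y[-1] - y[0])
    amp0 = max(abs(span), 1e-12)
    # time at half rise -> k_obs ~ ln2 / t_half
    half = y[0] + 0.5 * span
    idx = np.nonzero(y >= half)[0] if span >= 0 else np.nonzero(y <= half)[0]
    t_half = float(t[idx[0]]) if idx.size else float(t[t.size // 2])
    k0 = math.log(2.0) / max(t_half, float(t[1] - t[0]))

    params = lmfit.Parameters()
    params.add("delta_f_max", value=amp0, min=0.0)
    params.add("k_obs", value=k0, min=1e-9)
    params.add("offset_c", value=float(y[0]))

    def residual(p):
        return (
            p["delta_f_max"] * (1.0 - np.exp(-p["k_obs"] * t)) + p["offset_c"] - y
        )

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailureError("association fit did not converge", diagnostics=result)
    k_obs = float(result.params["k_obs"].value)
    if t[-1] * k_obs < 3.0:
        import warnings

        warnings.warn(
            "trace spans < 3/k_obs; k_obs may be poorly constrained",
            RuntimeWarning,
            stacklevel=2,
        )
    stderr = {
        k: (v.stderr if v.stderr is not None else float("nan"))
        for k, v in result.params.items()
    }
    return AssociationFit(
        k_obs=k_obs,
        delta_f_max=float(result.params["delta_f_max"].value),
        offset_c=float(result.params["offset_c"].value),
        stderr=stderr,
    )


def _aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian residual model."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return float("inf")
    return aic + 2 * k * (k + 1) / denom


def _peel_biexponential_guess(t: np.ndarray, y: np.ndarray, c0: float):
    """Log-linear peeling: fit the slow tail first, then the fast residual."""
    z = y - c0
    z = np.clip(z, 1e-12, None)
    n = t.size
    tail = slice(max(n // 2, n - max(n // 3, 4)), n)
    coef_slow = np.polyfit(t[tail], np.log(z[tail]), 1)
    k_slow = max(-coef_slow[0], 1e-6)
    a_slow = math.exp(coef_slow[1])
    resid = y - c0 - a_slow * np.exp(-k_slow * t)
    head = resid[: max(n // 3, 4)] > 1e-12
    th, rh = t[: max(n // 3, 4)][head], resid[: max(n // 3, 4)][head]
    if th.size >= 2:
        coef_fast = np.polyfit(th, np.log(rh), 1)
        k_fast = max(-coef_fast[0], k_slow * 5)
        a_fast = math.exp(coef_fast[1])
    else:
        k_fast, a_fast = k_slow * 10, a_slow
    return (a_fast, k_fast), (a_slow, k_slow)


def _fit_single_decay(t, y):
    params = lmfit.Parameters()
    amp0 = max(float(y[0] - y[-1]), 1e-12)
    span = y[0] - y[-1]
    half = y[-1] + 0.5 * span
    idx = np.nonzero(y <= half)[0]
    t_half = float(t[idx[0]]) if idx.size else float(t[t.size // 2])
    params.add("amp", value=amp0, min=0.0)
    params.add("rate", value=math.log(2.0) / max(t_half, 1e-9), min=1e-9)
    params.add("offset_c", value=float(y[-1]))

    def residual(p):
        return p["amp"] * np.exp(-p["rate"] * t) + p["offset_c"] - y

    return lmfit.minimize(residual, params, method="leastsq")


def _fit_double_decay(t, y):
    """Multi-start biexponential fit.

    Starts from (a) the log-linear peeling guess and (b) a guess derived
    from the single-exponential fit (rates bracketing it), keeping the
    converged result with the lowest residual sum of squares; peeling
    alone is fragile when the tail anchor point is noisy.
    """

    def residual(p):
        return (
            p["amp1"] * np.exp(-p["rate1"] * t)
            + p["amp2"] * np.exp(-p["rate2"] * t)
            + p["offset_c"]
            - y
        )

    n_tail = max(3, t.size // 20)
    c0 = float(np.mean(y[-n_tail:]))
    starts = []
    try:
        (a_fast, k_fast), (a_slow, k_slow) = _peel_biexponential_guess(t, y, c0)
        starts.append((a_fast, k_fast, a_slow, k_slow, c0))
    except Exception:
        pass
    try:
        single = _fit_single_decay(t, y)
        if single.success:
            k = float(single.params["rate"].value)
            a = float(single.params["amp"].value)
            c = float(single.params["offset_c"].value)
            starts.append((0.5 * a, 4.0 * k, 0.5 * a, k / 3.0, c))
    except Exception:
        pass
    if not starts:
        starts.append((1.0, 1.0 / max(t[1] - t[0], 1e-9), 1.0,
                       1.0 / max(t[-1], 1e-9), c0))

    best = None
    for a1, k1, a2, k2, c in starts:
        params = lmfit.Parameters()
        params.add("amp1", value=max(a1, 1e-12), min=0.0)
        params.add("rate1", value=max(k1, 1e-9), min=1e-9)
        params.add("amp2", value=max(a2, 1e-12), min=0.0)
        params.add("rate2", value=max(k2, 1e-9), min=1e-9)
        params.add("offset_c", value=c)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise FitFailureError("double-exponential fit did not converge")
    return best[1]


def fit_dissociation(trace: KineticTrace, model: str = "auto") -> DissociationFit:
    """Fit a single or double exponential decay on t >= dead_time.

    With ``model='auto'`` both candidates are fitted and the one with the
    lower corrected Akaike information criterion (AICc) is returned; the
    AICc of both candidates is reported either way. A double fit whose two
    rates collapse within 1% of each other degenerates to the single model.
    """
    if model not in ("single", "double", "auto"):
        raise InvalidArgumentError("model must be single, double or auto")
    t, y = trace.analysis_window()
    if t.size < 6:
        raise InsufficientDataError("need >= 6 points beyond the dead time")

    results: dict[str, object] = {}
    aicc: dict[str, float] = {}

    def try_fit(name, fn):
        try:
            res = fn(t, y)
        except Exception:
            return
        if res.success:
            results[name] = res
            aicc[name] = _aicc(float(np.sum(res.residual**2)), t.size, res.nvarys)

    if model in ("single", "auto"):
        try_fit("single", _fit_single_decay)
    if model in ("double", "auto"):
        try_fit("double", _fit_double_decay)

    if not results:
        raise FitFailureError("no dissociation model converged")

    def double_is_degenerate() -> bool:
        """A double fit whose rates collapse or whose minor amplitude
        vanishes carries no evidence for a second component."""
        p = results["double"].params
        r1, r2 = float(p["rate1"].value), float(p["rate2"].value)
        a1, a2 = float(p["amp1"].value), float(p["amp2"].value)
        total = a1 + a2
        if abs(r1 - r2) <= 0.01 * max(r1, r2):
            return True
        return total <= 0 or min(a1, a2) / total < 0.01

    if model == "auto":
        if "double" in results and "single" in results and double_is_degenerate():
            chosen = "single"
        else:
            chosen = min(aicc, key=aicc.get)
    else:
        chosen = model
        if chosen not in results:
            raise FitFailureError(f"{chosen}-exponential fit did not converge")

    if chosen == "double":
        p = results["double"].params
        r1, r2 = float(p["rate1"].value), float(p["rate2"].value)
        if abs(r1 - r2) <= 0.01 * max(r1, r2):
            import warnings

            warnings.warn(
                "double-exponential rates degenerate; falling back to single",
                RuntimeWarning,
                stacklevel=2,
            )
            if "single" not in results:
                try_fit("single", _fit_single_decay)
            if "single" not in results:
                raise FitFailureError("single fallback did not converge")
            chosen = "single"

    res = results[chosen]
    stderr = {
        k: (v.stderr if v.stderr is not None else float("nan"))
        for k, v in res.params.items()
    }
    if chosen == "single":
        return DissociationFit(
            model="single",
            rates=(float(res.params["rate"].value),),
            amplitudes=(float(res.params["amp"].value),),
            offset_c=float(res.params["offset_c"].value),
            stderr=stderr,
            information_criterion=dict(aicc),
        )
    p = res.params
    pairs = sorted(
        [
            (float(p["rate1"].value), float(p["amp1"].value)),
            (float(p["rate2"].value), float(p["amp2"].value)),
        ],
        reverse=True,
    )
    return DissociationFit(
        model="double",
        rates=(pairs[0][0], pairs[1][0]),
        amplitudes=(pairs[0][1], pairs[1][1]),
        offset_c=float(p["offset_c"].value),
        stderr=stderr,
        information_criterion=dict(aicc),
    )


def association_rate_constant(
    k_obs: float, k_off: float, inputs: PartitioningInputs
) -> RateResult:
    """Mole-fraction association rate constant.

    k_on,x = (k_obs - k_off) * [H2O]/[L], with [L] the post-mixing
    accessible lipid concentration.
    """
    if k_off < 0:
        raise InvalidArgumentError("k_off must be >= 0")
    if k_obs <= k_off:
        raise NonPositiveRateError(
            f"k_obs ({k_obs}/s) must exceed k_off ({k_off}/s)"
        )
    water_um = inputs.water_molarity * 1e6
    kon_x = (k_obs - k_off) * water_um / inputs.accessible_lipid
    return RateResult(
        kon_x=kon_x,
        k_obs=k_obs,
        k_off=k_off,
        water_molarity=inputs.water_molarity,
        accessible_lipid=inputs.accessible_lipid,
    )


def normalize_trace(
    trace: KineticTrace, fit: Union[AssociationFit, DissociationFit]
) -> KineticTrace:
    """Map signal to (F - C)/(total amplitude)."""
    total = fit.total_amplitude
    if total <= 0:
        raise DegenerateAmplitudeError("total amplitude must be > 0")
    return trace.with_signal((trace.signal - fit.offset_c) / total)
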