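"""Three-state sequential kinetics for pump-probe action transients.

The model: a pump pulse promotes the anion to a bright upper state (S2),
which converts internally to the trapped dark state (S1) with lifetime
tau_fast, which in turn decays to the ground state (S0) with lifetime
tau_slow:

    S2 --(1/tau_fast)--> S1 --(1/tau_slow)--> S0

The prompt action channel detects the excited-state population (a weighted
sum of S2 and S1), the delayed channel detects ground-state recovery (S0).
Both are convolved with a Gaussian instrument response of width irf_sigma;
each exponential component then becomes the closed-form exponentially
modified Gaussian

    c(t) = A/2 * exp(sigma^2/(2 tau^2) - (t-t0)/tau)
               * erfc((sigma/tau - (t-t0)/sigma) / sqrt(2)).

Fitting is weighted nonlinear least squares (lmfit); the two lifetimes are
optimized in log-space to enforce positivity, shared between the prompt and
delayed channels, and canonically ordered tau_fast <= tau_slow afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc, erfcx

import lmfit

__all__ = [
    "KineticParams",
    "Transient",
    "FitResult",
    "populations",
    "convolve_irf",
    "prompt_signal",
    "delayed_signal",
    "fit_transients",
]

#: below this relative rate difference the degenerate k1 = k2 limit is used
_EQUAL_RATE_TOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the sequential model plus detection weights.

    Times are in seconds.  amp_s2/amp_s1 weight the prompt channel,
    amp_s0 the delayed channel; baseline is per-channel constant offset
    (the same value is used for both unless the fit frees them separately).
    """

    tau_fast: float
    tau_slow: float
    amp_s2: float = 1.0
    amp_s1: float = 0.5
    amp_s0: float = 1.0
    baseline: float = 0.0
    t0: float = 0.0
    irf_sigma: float = 80e-15

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("lifetimes must be positive")
        if self.irf_sigma < 0:
            raise ValueError("IRF width must be nonnegative")
        if min(self.amp_s2, self.amp_s1, self.amp_s0) < 0:
            raise ValueError("detection weights must be nonnegative")

    def ordered(self) -> "KineticParams":
        """Canonical label order tau_fast <= tau_slow (swaps weights along)."""
        if self.tau_fast <= self.tau_slow:
            return self
        return replace(
            self, tau_fast=self.tau_slow, tau_slow=self.tau_fast,
            amp_s2=self.amp_s1, amp_s1=self.amp_s2,
        )


@dataclass
class Transient:
    """A measured or synthetic pump-probe delay scan of one action channel."""

    delays: np.ndarray  # seconds
    signal: np.ndarray
    sigma: np.ndarray | None = None
    channel: str = "prompt"  # "prompt" | "delayed"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.channel not in ("prompt", "delayed"):
            raise ValueError(f"channel must be 'prompt' or 'delayed', got {self.channel!r}")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("per-point uncertainties must be positive")


@dataclass
class FitResult:
    """Converged fit with 1-sigma uncertainties from the covariance."""

    params: KineticParams
    uncertainties: dict[str, float]
    covariance: np.ndarray | None
    redchi: float
    converged: bool
    message: str = ""
    baseline_delayed: float | None = None


def populations(
    t: np.ndarray | float, tau_fast: float, tau_slow: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Populations (P_S2, P_S1, P_S0) of the sequential model at delay t >= 0.

    P_S2 = e^{-k1 t};  P_S1 = k1/(k2-k1) (e^{-k1 t} - e^{-k2 t});
    P_S0 = 1 - P_S2 - P_S1, so conservation is exact by construction.
    The analytic degenerate limit k t e^{-k t} is used when k1 ~ k2.
    """
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("lifetimes must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("the unconvolved model is one-sided: t must be >= 0")
    k1, k2 = 1.0 / tau_fast, 1.0 / tau_slow
    p2 = np.exp(-k1 * t_arr)
    if abs(k1 - k2) / k1 < _EQUAL_RATE_TOL:
        p1 = k1 * t_arr * np.exp(-k1 * t_arr)
    else:
        p1 = k1 / (k2 - k1) * (np.exp(-k1 * t_arr) - np.exp(-k2 * t_arr))
    p0 = 1.0 - p2 - p1
    return p2, p1, p0


def convolve_irf(
    tau: float,
    amplitude: float,
    t: np.ndarray | float,
    t0: float = 0.0,
    irf_sigma: float = 0.0,
) -> np.ndarray:
    """One exponential decay component convolved with a Gaussian IRF.

    Closed-form exponentially modified Gaussian; irf_sigma = 0 reduces to
    the step-on exponential A e^{-(t-t0)/tau} H(t-t0).  Evaluated through
    erfcx where the naive formula would overflow.
    """
    if tau <= 0:
        raise ValueError("component lifetime must be positive")
    if irf_sigma < 0:
        raise ValueError("IRF width must be nonnegative")
    scalar = np.isscalar(t)
    x = np.atleast_1d(np.asarray(t, dtype=float)) - t0
    if irf_sigma == 0.0:
        out = np.where(x >= 0, amplitude * np.exp(-np.clip(x, 0, None) / tau), 0.0)
        return float(out[0]) if scalar else out
    s = irf_sigma
    z = (s / tau - x / s) / np.sqrt(2.0)
    # exp(s^2/2tau^2 - x/tau) erfc(z) == erfcx(z) exp(-x^2/2s^2); the right
    # side is stable for moderate z, the left for very negative z (late t)
    out = np.empty_like(z)
    late = z < -20.0
    out[~late] = erfcx(z[~late]) * np.exp(-(x[~late] ** 2) / (2 * s * s))
    out[late] = 2.0 * np.exp(s * s / (2 * tau * tau) - x[late] / tau)
    result = 0.5 * amplitude * out
    return float(result[0]) if scalar else result


def _convolved_populations(
    t: np.ndarray, tau_fast: float, tau_slow: float, t0: float, irf_sigma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRF-convolved (P_S2, P_S1, P_S0); each exponential convolved exactly."""
    k1, k2 = 1.0 / tau_fast, 1.0 / tau_slow
    c_fast = convolve_irf(tau_fast, 1.0, t, t0, irf_sigma)
    p2 = c_fast
    if abs(k1 - k2) / k1 < _EQUAL_RATE_TOL:
        # degenerate limit: convolve k t e^{-kt} by finite difference of
        # two nearly equal rates (stable and within the model tolerance)
        eps = 1e-6
        c2 = convolve_irf(tau_slow * (1 + eps), 1.0, t, t0, irf_sigma)
        p1 = (c2 - c_fast) / eps * (k1 * tau_slow)
    else:
        c_slow = convolve_irf(tau_slow, 1.0, t, t0, irf_sigma)
        p1 = k1 / (k2 - k1) * (c_fast - c_slow)
    # convolved unit step (total excited fraction created by the pump)
    if irf_sigma == 0.0:
        step = (np.asarray(t, dtype=float) >= t0).astype(float)
    else:
        step = 0.5 * erfc(-(np.asarray(t, dtype=float) - t0) / (np.sqrt(2) * irf_sigma))
    p0 = step - p2 - p1
    return p2, p1, p0


def prompt_signal(params: KineticParams, t: np.ndarray | float) -> np.ndarray:
    """Prompt action channel: baseline + IRF-convolved (a2 P_S2 + a1 P_S1)."""
    p2, p1, _ = _convolved_populations(
        np.atleast_1d(np.asarray(t, dtype=float)),
        params.tau_fast, params.tau_slow, params.t0, params.irf_sigma,
    )
    return params.baseline + params.amp_s2 * p2 + params.amp_s1 * p1


def delayed_signal(params: KineticParams, t: np.ndarray | float) -> np.ndarray:
    """Delayed action channel: baseline + IRF-convolved a0 P_S0 (recovery)."""
    _, _, p0 = _convolved_populations(
        np.atleast_1d(np.asarray(t, dtype=float)),
        params.tau_fast, params.tau_slow, params.t0, params.irf_sigma,
    )
    return params.baseline + params.amp_s0 * p0


_PARAM_NAMES = (
    "tau_fast", "tau_slow", "amp_s2", "amp_s1", "amp_s0",
    "baseline", "t0", "irf_sigma",
)


def fit_transients(
    prompt: Transient,
    delayed: Transient | None = None,
    init: KineticParams | None = None,
    fixed: set[str] | frozenset[str] = frozenset(),
) -> FitResult:
    """Joint weighted least-squares fit of the sequential model.

    The two lifetimes, t0 and irf_sigma are shared between channels;
    amplitudes and baselines are per-channel.  Lifetimes are fit as
    log10(tau) to enforce positivity; ``fixed`` names parameters held at
    their initial values.  Non-convergent or degenerate fits come back
    flagged, never silently.
    """
    if init is None:
        raise ValueError("an initial KineticParams guess is required")
    n_pts = len(prompt.delays) + (len(delayed.delays) if delayed is not None else 0)
    if n_pts < 8:
        raise ValueError(f"need at least 8 points across channels, got {n_pts}")
    for tr in (prompt, delayed):
        if tr is not None and np.ptp(tr.signal) == 0:
            return FitResult(init, {}, None, np.nan, False, "degenerate data: constant signal")

    p = lmfit.Parameters()
    p.add("log10_tau_fast", value=np.log10(init.tau_fast), vary="tau_fast" not in fixed)
    p.add("log10_tau_slow", value=np.log10(init.tau_slow), vary="tau_slow" not in fixed)
    p.add("amp_s2", value=init.amp_s2, min=0.0, vary="amp_s2" not in fixed)
    p.add("amp_s1", value=init.amp_s1, min=0.0, vary="amp_s1" not in fixed)
    p.add("baseline_prompt", value=init.baseline, vary="baseline" not in fixed)
    # time-zero and IRF width are fit in picoseconds so the optimizer's
    # finite-difference steps are sensibly scaled
    p.add("t0_ps", value=init.t0 / 1e-12, vary="t0" not in fixed)
    p.add("irf_sigma_ps", value=max(init.irf_sigma, 1e-18) / 1e-12, min=0.0,
          vary="irf_sigma" not in fixed)
    if delayed is not None:
        p.add("amp_s0", value=init.amp_s0, min=0.0, vary="amp_s0" not in fixed)
        p.add("baseline_delayed", value=init.baseline, vary="baseline" not in fixed)

    def _params_from(v, which: str) -> KineticParams:
        base = v["baseline_prompt"] if which == "prompt" else v["baseline_delayed"]
        return KineticParams(
            tau_fast=10.0 ** v["log10_tau_fast"],
            tau_slow=10.0 ** v["log10_tau_slow"],
            amp_s2=v["amp_s2"], amp_s1=v["amp_s1"],
            amp_s0=v["amp_s0"] if "amp_s0" in v else 0.0,
            baseline=base, t0=v["t0_ps"] * 1e-12, irf_sigma=v["irf_sigma_ps"] * 1e-12,
        )

    def residual(pars):
        v = {name: par.value for name, par in pars.items()}
        res = []
        model_p = prompt_signal(_params_from(v, "prompt"), prompt.delays)
        w = prompt.sigma if prompt.sigma is not None else np.ones_like(prompt.signal)
        res.append((prompt.signal - model_p) / w)
        if delayed is not None:
            model_d = delayed_signal(_params_from(v, "delayed"), delayed.delays)
            wd = delayed.sigma if delayed.sigma is not None else np.ones_like(delayed.signal)
            res.append((delayed.signal - model_d) / wd)
        return np.concatenate(res)

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        return FitResult(init, {}, None, np.nan, False, out.message)

    v = {name: par.value for name, par in out.params.items()}
    fitted = _params_from(v, "prompt").ordered()
    # propagate 1-sigma errors; lifetimes back-transformed from log10 space
    errs: dict[str, float] = {}
    ln10 = np.log(10.0)
    for name, par in out.params.items():
        if par.stderr is None:
            continue
        if name == "log10_tau_fast":
            errs["tau_fast"] = par.stderr * ln10 * 10.0 ** par.value
        elif name == "log10_tau_slow":
            errs["tau_slow"] = par.stderr * ln10 * 10.0 ** par.value
        elif name == "t0_ps":
            errs["t0"] = par.stderr * 1e-12
        elif name == "irf_sigma_ps":
            errs["irf_sigma"] = par.stderr * 1e-12
        else:
            errs[name] = par.stderr
    if fitted.tau_fast != 10.0 ** v["log10_tau_fast"] and "tau_fast" in errs and "tau_slow" in errs:
        errs["tau_fast"], errs["tau_slow"] = errs["tau_slow"], errs["tau_fast"]
    cov = out.covar if hasattr(out, "covar") else None
    return FitResult(
        fitted, errs, cov, float(out.redchi), True, out.message,
        baseline_delayed=v.get("baseline_delayed"),
    )
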