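"""3-state step/turn hidden Markov model: likelihood, fitting, decoding.

Observables per trip are planar step lengths (km) and signed turning angles
(radians, (−π, π]).  Each behavioural state emits steps from a gamma
distribution (parameterised by mean/sd) and turns from a von Mises
distribution; the latent state follows a first-order Markov chain.  Fitting
is direct numerical maximum likelihood (quasi-Newton on a working scale:
log for positive parameters, multinomial logit for transition rows and the
initial law), not EM.  States are always reported in ascending step-mean
order: resting < foraging < transiting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, logsumexp

from movekba.synthetic import STATE_NAMES, GeneratorConfig

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class StepTurnSeries:
    """Observables of one trip: steps (length T−1) and turns (same length,
    NaN where undefined — always at index 0, the first fix of the trip)."""

    steps: np.ndarray
    turns: np.ndarray
    trip_id: str = ""

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        self.turns = np.asarray(self.turns, dtype=float)
        if self.steps.shape != self.turns.shape:
            raise ValueError("steps and turns must be aligned 1:1")
        if np.any(np.isnan(self.steps)):
            idx = int(np.flatnonzero(np.isnan(self.steps))[0])
            raise ValueError(f"NaN step at index {idx} in trip {self.trip_id!r}")
        if np.any(self.steps < 0):
            raise ValueError("negative step length")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class HMMParams:
    """Parameters of the 3-state model; arrays are ordered (resting,
    foraging, transiting) i.e. ascending step mean."""

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mu: np.ndarray
    turn_kappa: np.ndarray
    gamma: np.ndarray  # 3x3 row-stochastic transition matrix
    delta: np.ndarray  # initial distribution
    zero_mass: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "turn_mu", "turn_kappa", "zero_mass"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step means and sds must be positive")
        if np.any(self.turn_kappa < 0):
            raise ValueError("von Mises concentration must be non-negative")

    def relabelled_by_step_mean(self) -> "HMMParams":
        """Canonical state order: ascending step mean."""
        order = np.argsort(self.step_mean)
        return HMMParams(
            step_mean=self.step_mean[order],
            step_sd=self.step_sd[order],
            turn_mu=self.turn_mu[order],
            turn_kappa=self.turn_kappa[order],
            gamma=self.gamma[np.ix_(order, order)],
            delta=self.delta[order],
            zero_mass=self.zero_mass[order],
        )

    @classmethod
    def from_config(cls, config: GeneratorConfig) -> "HMMParams":
        em = config.emissions
        return cls(
            step_mean=[e.step_mean for e in em],
            step_sd=[e.step_sd for e in em],
            turn_mu=[e.turn_mu for e in em],
            turn_kappa=[e.turn_kappa for e in em],
            gamma=np.asarray(config.transition_matrix, float),
            delta=np.asarray(config.initial_distribution, float),
        )


@dataclass
class DecodedTrack:
    """Viterbi decoding of one trip: one state label per fix with a step."""

    trip_id: str
    states: np.ndarray  # int labels, length = len(series)

    @property
    def state_names(self) -> list[str]:
        return [STATE_NAMES[s] for s in self.states]


@dataclass
class HMMFitResult:
    params: HMMParams
    loglik: float
    converged: bool
    n_restarts: int
    message: str = ""


def steps_and_turns(xy, trip_id: str = "") -> StepTurnSeries:
    """Step lengths and turning angles from projected positions.

    *xy* is an (T, 2) array or a DataFrame with x, y columns, T ≥ 3.
    Step t is the planar distance from fix t to t+1; turn t (t ≥ 1) is the
    signed heading change at fix t, wrapped to (−π, π]; turn 0 is NaN.
    """
    if isinstance(xy, pd.DataFrame):
        xy = xy[["x", "y"]].to_numpy()
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 fixes for steps and turns")
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = np.full(len(steps), np.nan)
    raw = np.diff(headings)
    turns[1:] = -(np.mod(-raw + np.pi, 2 * np.pi) - np.pi)  # wrap to (−π, π]
    return StepTurnSeries(steps=steps, turns=turns, trip_id=trip_id)


def _gamma_logpdf(x, mean, sd):
    """Gamma log-density parameterised by mean/sd (shape=(mean/sd)², rate=mean/sd²)."""
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    with np.errstate(divide="ignore"):
        return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _vonmises_logpdf(x, mu, kappa):
    # exp-scaled Bessel keeps this finite for large kappa
    return kappa * (np.cos(x - mu) - 1.0) - _LOG_2PI - np.log(i0e(kappa))


def emission_density(params: HMMParams, state: int, step: float, turn: float | None) -> float:
    """Joint emission density of one (step, turn) pair under one state.

    The turn factor is omitted when *turn* is None/NaN (undefined at trip
    starts).  Zero steps carry the state's zero-inflation point mass.
    """
    if step < 0:
        raise ValueError("step length must be non-negative")
    zm = params.zero_mass[state]
    if step == 0.0:
        dens = zm if zm > 0 else 0.0
    else:
        dens = (1.0 - zm) * float(
            np.exp(_gamma_logpdf(step, params.step_mean[state], params.step_sd[state]))
        )
    if turn is not None and not np.isnan(turn):
        dens *= float(
            np.exp(_vonmises_logpdf(turn, params.turn_mu[state], params.turn_kappa[state]))
        )
    return dens


def _log_emission_matrix(params: HMMParams, series: StepTurnSeries) -> np.ndarray:
    """(T, 3) log joint emission densities for every observation and state."""
    steps = series.steps[:, None]
    turns = series.turns[:, None]
    mean = params.step_mean[None, :]
    sd = params.step_sd[None, :]
    zm = params.zero_mass[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logb = np.where(
            steps > 0,
            np.log1p(-zm) + _gamma_logpdf(np.maximum(steps, 1e-300), mean, sd),
            np.where(zm > 0, np.log(np.maximum(zm, 1e-300)), -np.inf),
        )
        vm = _vonmises_logpdf(
            np.where(np.isnan(turns), 0.0, turns), params.turn_mu[None, :],
            params.turn_kappa[None, :],
        )
        logb = logb + np.where(np.isnan(turns), 0.0, vm)
    return logb


def hmm_loglik(params: HMMParams, series_list: list[StepTurnSeries]) -> float:
    """Total log-likelihood over trips via the scaled forward algorithm.

    Trips of equal length are batched so the time recursion vectorises.
    """
    if not series_list:
        raise ValueError("need at least one series")
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(series_list):
        by_len.setdefault(len(s), []).append(i)
    total = 0.0
    for T, idxs in by_len.items():
        logb = np.stack(
            [_log_emission_matrix(params, series_list[i]) for i in idxs]
        )  # (S, T, 3)
        total += float(np.sum(_forward_batch(params, logb)))
    return total


def _forward_batch(params: HMMParams, logb: np.ndarray) -> np.ndarray:
    """Per-series log-likelihoods for a batch of equal-length series."""
    S, T, _ = logb.shape
    gamma = params.gamma
    m = logb[:, 0, :].max(axis=1, keepdims=True)
    alpha = params.delta[None, :] * np.exp(logb[:, 0, :] - m)
    c = alpha.sum(axis=1, keepdims=True)
    ll = np.log(c[:, 0]) + m[:, 0]
    alpha = alpha / c
    for t in range(1, T):
        m = logb[:, t, :].max(axis=1, keepdims=True)
        alpha = (alpha @ gamma) * np.exp(logb[:, t, :] - m)
        c = alpha.sum(axis=1, keepdims=True)
        ll += np.log(c[:, 0]) + m[:, 0]
        alpha = alpha / c
    return ll


def viterbi_decode(params: HMMParams, series: StepTurnSeries) -> DecodedTrack:
    """Most probable state sequence (log-space dynamic program).

    Backtracking ties break toward the lowest state index.
    """
    logb = _log_emission_matrix(params, series)
    T = len(series)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(params.gamma)
        log_delta = np.log(params.delta)
    score = log_delta + logb[0]
    back = np.zeros((T, 3), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + log_gamma  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(3)] + logb[t]
    states = np.empty(T, dtype=np.int64)
    states[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return DecodedTrack(trip_id=series.trip_id, states=states)


# ---------------------------------------------------------------------------
# fitting


def _pack(params: HMMParams, fit_zero: bool) -> np.ndarray:
    g = params.gamma
    eta = []
    for i in range(3):
        for j in range(3):
            if i != j:
                eta.append(np.log(max(g[i, j], 1e-12) / max(g[i, i], 1e-12)))
    dl = [np.log(max(params.delta[j], 1e-12) / max(params.delta[0], 1e-12)) for j in (1, 2)]
    parts = [
        np.log(params.step_mean),
        np.log(params.step_sd),
        params.turn_mu,
        np.log(np.maximum(params.turn_kappa, 1e-6)),
        np.array(eta),
        np.array(dl),
    ]
    if fit_zero:
        zm = np.clip(params.zero_mass, 1e-8, 1 - 1e-8)
        parts.append(np.log(zm / (1 - zm)))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, fit_zero: bool) -> HMMParams:
    step_mean = np.exp(theta[0:3])
    step_sd = np.exp(theta[3:6])
    turn_mu = -(np.mod(-theta[6:9] + np.pi, 2 * np.pi) - np.pi)
    turn_kappa = np.exp(theta[9:12])
    eta = theta[12:18]
    gamma = np.zeros((3, 3))
    k = 0
    for i in range(3):
        row = np.zeros(3)
        for j in range(3):
            if i != j:
                row[j] = eta[k]
                k += 1
        e = np.exp(row - row.max())
        e[i] = np.exp(-row.max())  # reference category: the diagonal
        gamma[i] = e / e.sum()
    dl = np.concatenate([[0.0], theta[18:20]])
    delta = np.exp(dl - logsumexp(dl))
    zero_mass = np.zeros(3)
    if fit_zero:
        zero_mass = 1.0 / (1.0 + np.exp(-theta[20:23]))
    return HMMParams(
        step_mean=step_mean, step_sd=step_sd, turn_mu=turn_mu,
        turn_kappa=turn_kappa, gamma=gamma, delta=delta, zero_mass=zero_mass,
    )


def fit_hmm(
    series_list: list[StepTurnSeries],
    init: HMMParams,
    n_restarts: int = 5,
    perturb_sd: float = 0.2,
    seed: int = 0,
    maxiter: int = 500,
) -> HMMFitResult:
    """Fit by direct numerical maximum likelihood with seeded multi-start.

    The first start is *init* itself; subsequent starts perturb the working
    parameters with N(0, perturb_sd²) noise.  The best of all converged (or
    best-found) optima is returned with states relabelled by ascending step
    mean.  Zero-inflation masses are estimated only when zero steps occur.
    """
    n_obs = sum(len(s) for s in series_list)
    fit_zero = any(np.any(s.steps == 0.0) for s in series_list)
    n_free = 20 + (3 if fit_zero else 0)
    if n_obs < 50 * n_free:
        logger.warning(
            "fit_hmm: %d observations for %d free parameters (< 50x) — "
            "estimates may be unstable", n_obs, n_free,
        )
    if fit_zero and np.all(init.zero_mass == 0):
        init = replace(init, zero_mass=np.full(3, 0.05))

    theta0 = _pack(init, fit_zero)
    rng = np.random.default_rng(seed)

    def nll(theta: np.ndarray) -> float:
        try:
            p = _unpack(theta, fit_zero)
            val = -hmm_loglik(p, series_list)
        except (ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    best = None
    any_converged = False
    for r in range(max(1, n_restarts)):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, perturb_sd, len(theta0))
        res = minimize(nll, start, method="L-BFGS-B", options={"maxiter": maxiter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    fitted = _unpack(best.x, fit_zero).relabelled_by_step_mean()
    loglik = -float(best.fun)
    init_ll = hmm_loglik(init, series_list)
    if loglik < init_ll - 1e-6:
        logger.warning(
            "fit_hmm: optimiser did not improve on the initial values "
            "(%.3f < %.3f)", loglik, init_ll,
        )
    return HMMFitResult(
        params=fitted,
        loglik=loglik,
        converged=any_converged,
        n_restarts=max(1, n_restarts),
        message=str(best.message),
    )


def state_proportions(
    decoded: list[DecodedTrack],
    colony_of: dict[str, str] | None = None,
    individuals_per_colony: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-colony behavioural proportions plus a colony-weighted grand mean.

    *colony_of* maps trip_id → colony_id (single pooled colony when None);
    weights are the number of tracked individuals per colony, accounting
    for differences in colony sample size (defaults to equal weights).
    Returns a frame indexed by colony (last row ``grand_mean``) with one
    column per state; rows sum to 1.
    """
    if not decoded:
        raise ValueError("need at least one decoded track")
    counts: dict[str, np.ndarray] = {}
    for d in decoded:
        colony = (colony_of or {}).get(d.trip_id, "all")
        c = counts.setdefault(colony, np.zeros(3))
        c += np.bincount(d.states, minlength=3)
    colonies = sorted(counts)
    props = {c: counts[c] / counts[c].sum() for c in colonies}
    if individuals_per_colony is None:
        weights = {c: 1.0 for c in colonies}
    else:
        weights = {c: float(individuals_per_colony.get(c, 0)) for c in colonies}
    wsum = sum(weights.values())
    grand = sum(props[c] * weights[c] for c in colonies) / wsum
    rows = {c: props[c] for c in colonies}
    rows["grand_mean"] = grand
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STATE_NAMES))
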