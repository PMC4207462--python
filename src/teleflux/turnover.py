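"""Two-state ("telegraph") stochastic protein-turnover model.

One gene is described by six rates: the promoter switches between OFF and ON
states (rates ``k_on``, ``k_off``), transcribes while ON (rate ``k_m``), mRNAs
degrade stochastically (rate ``gamma_m``), and the protein layer is
deterministic: ``dp/dt = k_p * m - gamma_p * p``.  Promoter and mRNA dynamics
are simulated exactly (Gillespie), the protein follows the closed-form
relaxation between stochastic events.

The module provides exact stationary moments, the stationary protein
autocorrelation function, the half-autocorrelation ("mixing") time, exact
simulation, stationary-state sampling, and parameterization from measurable
observables (mean levels, half-lives, mean promoter ON/OFF durations).

Units: hours for all times and rates; molecules per cell for mRNA (integer)
and protein (continuous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import expm
from scipy.optimize import brentq

LN2 = math.log(2.0)

__all__ = [
    "TurnoverParams",
    "TurnoverObservables",
    "GeneExpressionState",
    "StationaryMoments",
    "InvalidObservableError",
    "UnreachableMeanError",
    "NoStationaryStateError",
    "HorizonError",
    "params_from_observables",
    "stationary_moments",
    "protein_acf",
    "half_autocorrelation_time",
    "simulate_expression",
    "sample_stationary_state",
]


class InvalidObservableError(ValueError):
    """An observable is zero, negative, or otherwise unusable."""


class UnreachableMeanError(ValueError):
    """The requested stationary mean cannot be realized (e.g. gene never ON)."""


class NoStationaryStateError(ValueError):
    """The model has no (non-degenerate) stationary distribution."""


class HorizonError(RuntimeError):
    """The autocorrelation never reached the target within the search horizon."""


@dataclass(frozen=True)
class TurnoverParams:
    """The six rate constants of one gene's turnover model (all per hour).

    ``k_on``/``k_off`` are the promoter OFF->ON / ON->OFF switching rates,
    ``k_m`` the transcription rate while ON, ``gamma_m`` the mRNA degradation
    rate, ``k_p`` the translation rate (protein per mRNA per hour) and
    ``gamma_p`` the protein degradation rate.
    """

    k_on: float
    k_off: float
    k_m: float
    gamma_m: float
    k_p: float
    gamma_p: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_m", "gamma_m", "k_p", "gamma_p"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")

    @property
    def t_on(self) -> float:
        """Mean ON duration, 1/k_off (inf if the promoter never switches off)."""
        return 1.0 / self.k_off if self.k_off > 0 else math.inf

    @property
    def t_off(self) -> float:
        """Mean OFF duration, 1/k_on."""
        return 1.0 / self.k_on if self.k_on > 0 else math.inf

    @property
    def on_fraction(self) -> float:
        """Stationary probability of the ON state, k_on / (k_on + k_off)."""
        lam = self.k_on + self.k_off
        if lam == 0:
            raise NoStationaryStateError("promoter never switches (k_on = k_off = 0)")
        return self.k_on / lam


@dataclass(frozen=True)
class TurnoverObservables:
    """Measurable summary of one gene: means, half-lives, ON/OFF durations.

    Fields: ``mean_protein`` and ``mean_mrna`` in molecules per cell,
    ``protein_half_life``/``mrna_half_life``/``t_on``/``t_off`` in hours.
    """

    mean_protein: float
    mean_mrna: float
    protein_half_life: float
    mrna_half_life: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        for name in (
            "mean_protein",
            "mean_mrna",
            "protein_half_life",
            "mrna_half_life",
        ):
            v = getattr(self, name)
            if not v > 0 or not np.isfinite(v):
                raise InvalidObservableError(
                    f"observable {name} must be finite and > 0, got {v!r}"
                )
        # infinite ON/OFF durations encode a promoter locked in one state
        for name in ("t_on", "t_off"):
            v = getattr(self, name)
            if not v > 0:
                raise InvalidObservableError(
                    f"observable {name} must be > 0, got {v!r}"
                )


@dataclass
class GeneExpressionState:
    """Instantaneous state of one gene: promoter Boolean, mRNA count, protein level."""

    promoter_on: bool
    mrna: int
    protein: float

    def __post_init__(self) -> None:
        if self.mrna < 0 or int(self.mrna) != self.mrna:
            raise ValueError(f"mrna must be a non-negative integer, got {self.mrna!r}")
        if self.protein < 0:
            raise ValueError(f"protein must be >= 0, got {self.protein!r}")
        self.mrna = int(self.mrna)
        self.protein = float(self.protein)

    def copy(self) -> "GeneExpressionState":
        return GeneExpressionState(self.promoter_on, self.mrna, self.protein)


@dataclass(frozen=True)
class StationaryMoments:
    """Exact stationary first and second moments of mRNA and protein."""

    mean_mrna: float
    var_mrna: float
    cv_mrna: float
    mean_protein: float
    var_protein: float
    cv_protein: float
    # promoter-protein and mRNA-protein covariances are exposed because the
    # autocorrelation initial conditions are built from them
    cov_promoter_protein: float = field(default=0.0, repr=False)
    cov_mrna_protein: float = field(default=0.0, repr=False)


def params_from_observables(obs: TurnoverObservables) -> TurnoverParams:
    """Invert the stationary-mean identities to rates.

    k_off = 1/t_on, k_on = 1/t_off, degradation rates are ln2/half-life, and
    the synthesis rates are solved from mean_mrna = f * k_m / gamma_m and
    mean_protein = k_p * mean_mrna / gamma_p with f the promoter ON-fraction.
    """
    if not isinstance(obs, TurnoverObservables):
        obs = TurnoverObservables(**obs) if isinstance(obs, dict) else obs
    k_off = 1.0 / obs.t_on
    k_on = 1.0 / obs.t_off
    f = k_on / (k_on + k_off)
    if f == 0 and obs.mean_mrna > 0:
        raise UnreachableMeanError("gene never ON but a positive mean mRNA requested")
    gamma_m = LN2 / obs.mrna_half_life
    gamma_p = LN2 / obs.protein_half_life
    k_m = obs.mean_mrna * gamma_m / f
    k_p = obs.mean_protein * gamma_p / obs.mean_mrna
    return TurnoverParams(k_on, k_off, k_m, gamma_m, k_p, gamma_p)


def stationary_moments(params: TurnoverParams) -> StationaryMoments:
    """Exact stationary moments of the telegraph model with deterministic protein.

    Derived from the moment equations of the promoter/mRNA master equation
    coupled to the linear protein ODE (the drift is linear in the state, so
    first and second moments close exactly):

        <m>      = f k_m / gamma_m
        Var(m)   = <m> [1 + k_m (1-f) / (lambda + gamma_m)]
        Cov(g,m) = f (1-f) k_m / (lambda + gamma_m)
        <p>      = k_p <m> / gamma_p
        Cov(g,p) = k_p Cov(g,m) / (lambda + gamma_p)
        Cov(m,p) = [k_p Var(m) + k_m Cov(g,p)] / (gamma_m + gamma_p)
        Var(p)   = k_p Cov(m,p) / gamma_p

    with lambda = k_on + k_off and f = k_on / lambda.
    """
    if params.gamma_m == 0 or params.gamma_p == 0:
        raise NoStationaryStateError("gamma_m and gamma_p must be > 0")
    lam = params.k_on + params.k_off
    if lam == 0:
        raise NoStationaryStateError("promoter never switches (k_on = k_off = 0)")
    f = params.k_on / lam
    gm, gp, km, kp = params.gamma_m, params.gamma_p, params.k_m, params.k_p
    mean_m = f * km / gm
    cov_gm = f * (1.0 - f) * km / (lam + gm)
    var_m = mean_m + (km / gm) * cov_gm
    mean_p = kp * mean_m / gp
    cov_gp = kp * cov_gm / (lam + gp)
    cov_mp = (kp * var_m + km * cov_gp) / (gm + gp)
    var_p = kp * cov_mp / gp
    cv_m = math.sqrt(var_m) / mean_m if mean_m > 0 else math.nan
    cv_p = math.sqrt(var_p) / mean_p if mean_p > 0 else math.nan
    return StationaryMoments(
        mean_mrna=mean_m,
        var_mrna=var_m,
        cv_mrna=cv_m,
        mean_protein=mean_p,
        var_protein=var_p,
        cv_protein=cv_p,
        cov_promoter_protein=cov_gp,
        cov_mrna_protein=cov_mp,
    )


def _acf_drift_matrix(params: TurnoverParams) -> np.ndarray:
    lam = params.k_on + params.k_off
    return np.array(
        [
            [-lam, 0.0, 0.0],
            [params.k_m, -params.gamma_m, 0.0],
            [0.0, params.k_p, -params.gamma_p],
        ]
    )


def protein_acf(params: TurnoverParams, lag: float | np.ndarray) -> float | np.ndarray:
    """Normalized stationary autocorrelation of the protein level.

    By the regression theorem for processes with linear drift, the vector
    ``C(tau) = Cov(p(0), [g, m, p](tau))`` obeys ``dC/dtau = A C`` with the
    drift matrix ``A`` of the mean dynamics; the ACF is the protein component
    of ``expm(A tau) C(0)`` normalized by Var(p).  Evaluating through the
    matrix exponential keeps degenerate (equal-rate) cases exact.
    """
    lags = np.atleast_1d(np.asarray(lag, dtype=float))
    if np.any(lags < 0):
        raise ValueError("lag must be >= 0")
    mom = stationary_moments(params)
    if mom.var_protein <= 0:
        raise NoStationaryStateError("protein variance is zero; ACF undefined")
    A = _acf_drift_matrix(params)
    c0 = np.array([mom.cov_promoter_protein, mom.cov_mrna_protein, mom.var_protein])
    out = np.array([(expm(A * t) @ c0)[2] for t in lags]) / mom.var_protein
    return out if np.ndim(lag) else float(out[0])


def half_autocorrelation_time(
    params: TurnoverParams,
    xtol: float = 1e-3,
    horizon: float | None = None,
) -> float:
    """Smallest lag at which the protein ACF equals 1/2 ("mixing time").

    Found by bracketing (doubling from the slowest relaxation timescale up to
    ``horizon``) followed by bisection to ``xtol`` hours.  Raises
    :class:`HorizonError` if the ACF stays above 1/2 over the whole horizon.
    """
    mom = stationary_moments(params)
    if mom.var_protein <= 0:
        raise NoStationaryStateError("protein variance is zero; ACF undefined")
    scale = max(
        1.0 / params.gamma_p,
        1.0 / params.gamma_m,
        1.0 / (params.k_on + params.k_off),
    )
    if horizon is None:
        horizon = 1000.0 * scale
    hi = scale
    while protein_acf(params, hi) > 0.5:
        hi *= 2.0
        if hi > horizon:
            raise HorizonError(
                f"ACF still above 1/2 at lag {horizon:.3g} h; increase horizon"
            )
    return float(brentq(lambda t: protein_acf(params, t) - 0.5, 0.0, hi, xtol=xtol))


# ---------------------------------------------------------------------------
# Exact stochastic simulation (Gillespie over the four stochastic reactions,
# protein updated with the exact exponential-relaxation solution between events)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _protein_step(p, m, kp, gp, dt):
    if gp > 0.0:
        pinf = kp * m / gp
        return pinf + (p - pinf) * math.exp(-gp * dt)
    return p + kp * m * dt


@njit(cache=True)
def _ssa_trajectory(
    k_on, k_off, km, gm, kp, gp, g0, m0, p0, duration, seed, t_out, g_out, m_out, p_out
):
    """Fill event-time records; returns the number of records needed.

    If the return value exceeds the capacity of the output arrays the caller
    must re-run with larger arrays (the seed makes the path reproducible).
    """
    np.random.seed(seed)
    cap = t_out.shape[0]
    t = 0.0
    g, m, p = g0, m0, p0
    n = 0
    if n < cap:
        t_out[n] = 0.0
        g_out[n] = g
        m_out[n] = m
        p_out[n] = p
    n += 1
    while True:
        a_sw = k_on if g == 0 else k_off
        a_tx = km if g == 1 else 0.0
        a_dm = gm * m
        atot = a_sw + a_tx + a_dm
        if atot <= 0.0:
            break
        dt = -math.log(np.random.random()) / atot
        if t + dt >= duration:
            break
        p = _protein_step(p, m, kp, gp, dt)
        t += dt
        r = np.random.random() * atot
        if r < a_sw:
            g = 1 - g
        elif r < a_sw + a_tx:
            m += 1
        else:
            m -= 1
        if n < cap:
            t_out[n] = t
            g_out[n] = g
            m_out[n] = m
            p_out[n] = p
        n += 1
    # closing record at the end of the horizon
    p = _protein_step(p, m, kp, gp, duration - t)
    if n < cap:
        t_out[n] = duration
        g_out[n] = g
        m_out[n] = m
        p_out[n] = p
    n += 1
    return n


@njit(cache=True)
def _ssa_final_state(k_on, k_off, km, gm, kp, gp, g0, m0, p0, duration, seed):
    """End state only (used for burn-in sampling); exact same dynamics."""
    np.random.seed(seed)
    t = 0.0
    g, m, p = g0, m0, p0
    while True:
        a_sw = k_on if g == 0 else k_off
        a_tx = km if g == 1 else 0.0
        a_dm = gm * m
        atot = a_sw + a_tx + a_dm
        if atot <= 0.0:
            break
        dt = -math.log(np.random.random()) / atot
        if t + dt >= duration:
            break
        p = _protein_step(p, m, kp, gp, dt)
        t += dt
        r = np.random.random() * atot
        if r < a_sw:
            g = 1 - g
        elif r < a_sw + a_tx:
            m += 1
        else:
            m -= 1
    p = _protein_step(p, m, kp, gp, duration - t)
    return g, m, p


def _run_ssa_events(
    params: TurnoverParams,
    init: GeneExpressionState,
    duration: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw event-time arrays (t, promoter, mrna, protein) including t=0 and t=duration."""
    lam_guess = (
        params.k_on
        + params.k_off
        + params.k_m
        + params.gamma_m * (init.mrna + max(1.0, params.k_m / max(params.gamma_m, 1e-12)))
    )
    cap = int(duration * lam_guess * 1.5) + 1024
    while True:
        t_out = np.empty(cap)
        g_out = np.empty(cap, dtype=np.int64)
        m_out = np.empty(cap, dtype=np.int64)
        p_out = np.empty(cap)
        n = _ssa_trajectory(
            params.k_on,
            params.k_off,
            params.k_m,
            params.gamma_m,
            params.k_p,
            params.gamma_p,
            1 if init.promoter_on else 0,
            init.mrna,
            init.protein,
            float(duration),
            np.uint32(seed),
            t_out,
            g_out,
            m_out,
            p_out,
        )
        if n <= cap:
            return t_out[:n], g_out[:n], m_out[:n], p_out[:n]
        cap = int(n * 1.2) + 16


def simulate_expression(
    params: TurnoverParams,
    init: GeneExpressionState,
    duration: float,
    seed: int,
) -> pd.DataFrame:
    """Exact simulation of one gene over ``duration`` hours.

    Returns a tidy DataFrame with columns ``time``, ``promoter``, ``mrna``,
    ``protein``, one row per stochastic event (plus the initial and final
    states).  Reproducible given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    t, g, m, p = _run_ssa_events(params, init, float(duration), seed)
    return pd.DataFrame({"time": t, "promoter": g, "mrna": m, "protein": p})


def sample_stationary_state(
    params: TurnoverParams,
    n: int,
    seed: int,
    burnin_multiplier: float = 5.0,
) -> list[GeneExpressionState]:
    """Draw ``n`` approximate samples of the stationary joint law.

    Each sample is obtained by burn-in simulation from a deterministic start
    (mean mRNA/protein, promoter set by majority ON-fraction) for
    ``burnin_multiplier`` times the half-autocorrelation time.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.k_on == 0:
        # gene permanently OFF: stationary state is deterministic
        return [GeneExpressionState(False, 0, 0.0) for _ in range(n)]
    mom = stationary_moments(params)
    try:
        t_half = half_autocorrelation_time(params)
    except NoStationaryStateError:
        t_half = 1.0 / params.gamma_p
    burnin = burnin_multiplier * t_half
    g0 = 1 if params.on_fraction >= 0.5 else 0
    m0 = int(round(mom.mean_mrna))
    p0 = mom.mean_protein
    seeds = np.random.SeedSequence(seed).generate_state(n) >> np.uint32(1)
    out = []
    for i in range(n):
        g, m, p = _ssa_final_state(
            params.k_on,
            params.k_off,
            params.k_m,
            params.gamma_m,
            params.k_p,
            params.gamma_p,
            g0,
            m0,
            p0,
            burnin,
            np.uint32(seeds[i]),
        )
        out.append(GeneExpressionState(bool(g), int(m), float(p)))
    return out
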