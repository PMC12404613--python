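"""The mechanistic (Weisse-type) ODE model of cell growth.

The model tracks one cell of fixed mass ``M`` growing at rate ``lambda``:

* external nutrient is imported by transporter proteins and metabolised to
  a generic cellular "energy" by metabolic enzymes, both with
  Michaelis-Menten kinetics;
* energy activates transcription of four mRNA classes (ribosomal ``r``,
  transporter ``t``, enzyme ``m``, housekeeping ``q``), again
  Michaelis-Menten: the ribosomal class has its own threshold ``theta_r``
  and the three non-ribosomal classes share ``theta_x`` (``gamma =
  1/theta_x``); the ``q`` class is autoinhibited by its own protein;
* free ribosomes bind mRNAs by mass action (``k_b``/``k_u``) and the
  complexes translate at ``g(a) = g_max * a / (K_p + a)`` amino acids per
  minute, consuming one energy unit per residue;
* the growth (dilution) rate is total translation over mass,
  ``lambda = g(a) * sum(c_x) / M``, and dilutes every species.

A mutation rescales one of 9 interpretable parameters (grouped into
metabolism, nutrient efficiency, transcription, and translation processes;
see :data:`MUTABLE_PARAMS`) in its deleterious direction: rates and
efficiencies shrink (``theta * value``); Michaelis constants and the mRNA
degradation rate grow (``value / theta``).  Pairwise mutational scans
over cross-process parameter pairs compare the simulated double-mutant
fitness with the neutrality laws: pairs involving translation parameters
track the two-sector closed form ``1/(1/W_x + 1/W_y - 1)``, while the
remaining pairs track the Product law, the residual deviation being
controlled by the transcription nonlinearity (small ``gamma`` makes
transcription linear in energy and the Product law near-exact).

Steady states are computed two ways: stiff integration of the full ODE
system, and a reduced 5-unknown algebraic root problem (in ``log(a), log(r),
log(lambda), log(s_i), log(p_q)``) derived by eliminating the mRNA,
complex, and protein balances; the two routes agree to solver tolerance
and cross-check each other.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root as scipy_root

from .laws import LAWS, predict

__all__ = [
    "WeisseParams",
    "SteadyState",
    "PairScanResult",
    "ConvergenceError",
    "MUTABLE_PARAMS",
    "SPECIES",
    "derivatives",
    "growth_rate_of_state",
    "default_initial_state",
    "steady_state_growth",
    "mutate",
    "pair_scan",
    "cross_process_pairs",
    "deviation_matrix",
    "gamma_sweep",
]

logger = logging.getLogger(__name__)

#: State vector layout: internal nutrient, energy, free ribosomes, free
#: mRNA per class, ribosome-mRNA complex per class, non-ribosomal proteins.
SPECIES = (
    "s_i", "a", "r",
    "m_r", "m_t", "m_m", "m_q",
    "c_r", "c_t", "c_m", "c_q",
    "p_t", "p_m", "p_q",
)

#: The 9 mutable parameters: name -> (process, deleterious direction).
#:
#: The nutrient uptake chain (import + catabolism) is one process: its two
#: protein classes share the same transcription rate, so the model cannot
#: reallocate between them and their parameters are not independent
#: targets.  ``w_r`` and ``w_q`` are excluded because *reducing* either
#: increases the wild-type growth rate (verified numerically), so neither
#: has a deleterious multiplicative direction.  This grouping yields 28
#: cross-process pairs.
MUTABLE_PARAMS: Dict[str, Tuple[str, str]] = {
    "v_t": ("metabolism", "shrink"),
    "K_t": ("metabolism", "grow"),
    "v_m": ("metabolism", "shrink"),
    "K_m": ("metabolism", "grow"),
    "n_s": ("nutrient_efficiency", "shrink"),
    "w_e": ("transcription", "shrink"),
    "d_m": ("transcription", "grow"),
    "g_max": ("translation", "shrink"),
    "K_p": ("translation", "grow"),
}


class ConvergenceError(RuntimeError):
    """Steady-state computation failed; the message carries a trajectory
    summary (horizon reached, last growth rate, relative drift)."""


@dataclass(frozen=True)
class WeisseParams:
    """Full parameter vector; see ``data/weisse_wt.yaml`` for units and the
    wild-type defaults."""

    s_ext: float
    v_t: float
    K_t: float
    v_m: float
    K_m: float
    n_s: float
    w_r: float
    w_e: float
    w_q: float
    theta_r: float
    theta_x: float
    K_q: float
    h_q: float
    k_b: float
    k_u: float
    d_m: float
    g_max: float
    K_p: float
    M: float
    n_r: float
    n_x: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.h_q < 1:
            raise ValueError("h_q must be >= 1")

    @property
    def gamma(self) -> float:
        """Inverse transcription threshold, ``1/theta_x``."""
        return 1.0 / self.theta_x

    @classmethod
    def default(cls, **overrides) -> "WeisseParams":
        """The wild-type parameter asset, optionally with field overrides."""
        text = resources.files("neutrality.data").joinpath("weisse_wt.yaml").read_text()
        values = yaml.safe_load(text)
        values.update(overrides)
        return cls(**values)

    def with_gamma(self, gamma: float) -> "WeisseParams":
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        return replace(self, theta_x=1.0 / gamma)


def mutate(params: WeisseParams, target: str, theta: float) -> WeisseParams:
    """Apply a deleterious perturbation of size ``theta`` in (0, 1].

    Shrink-direction parameters are multiplied by ``theta``; grow-direction
    parameters (Michaelis constants) are divided by ``theta`` so every
    mutation is growth-non-increasing.
    """
    if target not in MUTABLE_PARAMS:
        raise ValueError(
            f"unknown mutable parameter {target!r}; "
            f"choose from {sorted(MUTABLE_PARAMS)}"
        )
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    _, direction = MUTABLE_PARAMS[target]
    value = getattr(params, target)
    return replace(params, **{target: value * theta if direction == "shrink" else value / theta})


# ---------------------------------------------------------------------------
# Full ODE system
# ---------------------------------------------------------------------------

def _derivatives_clipped(y: np.ndarray, p: WeisseParams) -> np.ndarray:
    s_i, a, r, m_r, m_t, m_m, m_q, c_r, c_t, c_m, c_q, p_t, p_m, p_q = np.maximum(y, 0.0)

    g_a = p.g_max * a / (p.K_p + a)
    v_imp = p_t * p.v_t * p.s_ext / (p.K_t + p.s_ext)
    v_cat = p_m * p.v_m * s_i / (p.K_m + s_i)
    act = a / (p.theta_x + a)
    om_r = p.w_r * a / (p.theta_r + a)
    om_t = p.w_e * act
    om_m = p.w_e * act
    om_q = p.w_q * act / (1.0 + (p_q / p.K_q) ** p.h_q)

    v_r = g_a * c_r / p.n_r
    v_t_ = g_a * c_t / p.n_x
    v_m_ = g_a * c_m / p.n_x
    v_q = g_a * c_q / p.n_x

    c_tot = c_r + c_t + c_m + c_q
    lam = g_a * c_tot / p.M

    def dm(om, m, c, v):
        return om - (lam + p.d_m) * m - p.k_b * r * m + p.k_u * c + v

    def dc(m, c, v):
        return p.k_b * r * m - p.k_u * c - v - lam * c

    d = np.empty(14)
    d[0] = v_imp - v_cat - lam * s_i
    d[1] = p.n_s * v_cat - g_a * c_tot - lam * a
    d[2] = (
        v_r - lam * r
        + (p.k_u * c_tot + (v_r + v_t_ + v_m_ + v_q))
        - p.k_b * r * (m_r + m_t + m_m + m_q)
    )
    d[3] = dm(om_r, m_r, c_r, v_r)
    d[4] = dm(om_t, m_t, c_t, v_t_)
    d[5] = dm(om_m, m_m, c_m, v_m_)
    d[6] = dm(om_q, m_q, c_q, v_q)
    d[7] = dc(m_r, c_r, v_r)
    d[8] = dc(m_t, c_t, v_t_)
    d[9] = dc(m_m, c_m, v_m_)
    d[10] = dc(m_q, c_q, v_q)
    d[11] = v_t_ - lam * p_t
    d[12] = v_m_ - lam * p_m
    d[13] = v_q - lam * p_q
    return d


def derivatives(state: np.ndarray, params: WeisseParams) -> np.ndarray:
    """Time derivative of the 14-component state (see :data:`SPECIES`)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (14,):
        raise ValueError(f"state must have shape (14,), got {state.shape}")
    if np.any(state < -1e-9):
        raise ValueError("state components must be non-negative")
    return _derivatives_clipped(state, params)


def growth_rate_of_state(state: np.ndarray, params: WeisseParams) -> float:
    """Instantaneous growth rate ``g(a) * sum(c_x) / M`` of a state."""
    a = max(float(state[1]), 0.0)
    c_tot = float(np.sum(np.maximum(state[7:11], 0.0)))
    return params.g_max * a / (params.K_p + a) * c_tot / params.M


def default_initial_state(params: WeisseParams) -> np.ndarray:
    """A standard non-zero seed state used to start integrations: a little
    of everything, so all fluxes can bootstrap."""
    y0 = np.zeros(14)
    y0[0] = 100.0    # s_i
    y0[1] = 1000.0   # a
    y0[2] = 10.0     # r
    y0[3:7] = 10.0   # mRNAs
    y0[7:11] = 10.0  # complexes
    y0[11:] = 1000.0  # proteins
    return y0


# ---------------------------------------------------------------------------
# Reduced steady-state system
# ---------------------------------------------------------------------------
# At steady state the mRNA/complex/protein balances are linear given
# (a, r, lambda, s_i, p_q):
#   c_x = k_b r omega_x / ((lambda + d_m) d_x + lambda k_b r),
#       d_x = k_u + lambda + g(a)/n_x
#   m_x = d_x c_x / (k_b r);     p_x = g(a) c_x / (n_x lambda)
# leaving five residual equations: growth definition, free-ribosome
# balance, q-protein self-consistency, energy balance, nutrient balance.

_CLASSES = ("r", "t", "m", "q")


def _reduced_state(u: np.ndarray, p: WeisseParams):
    u = np.clip(u, -60.0, 60.0)
    a, r, lam, s_i, p_q = np.exp(u)
    g_a = p.g_max * a / (p.K_p + a)
    act = a / (p.theta_x + a)
    omega = {
        "r": p.w_r * a / (p.theta_r + a),
        "t": p.w_e * act,
        "m": p.w_e * act,
        "q": p.w_q * act / (1.0 + (p_q / p.K_q) ** p.h_q),
    }
    length = {"r": p.n_r, "t": p.n_x, "m": p.n_x, "q": p.n_x}
    c = {}
    m = {}
    for x in _CLASSES:
        d_x = p.k_u + lam + g_a / length[x]
        c[x] = p.k_b * r * omega[x] / ((lam + p.d_m) * d_x + lam * p.k_b * r)
        m[x] = d_x * c[x] / (p.k_b * r)
    prot = {x: g_a * c[x] / (length[x] * lam) for x in ("t", "m", "q")}
    return a, r, lam, s_i, p_q, g_a, omega, c, m, prot


def _reduced_residuals(u: np.ndarray, p: WeisseParams) -> np.ndarray:
    a, r, lam, s_i, p_q, g_a, omega, c, m, prot = _reduced_state(u, p)
    c_tot = sum(c.values())
    v_cat = prot["m"] * p.v_m * s_i / (p.K_m + s_i)
    v_imp = prot["t"] * p.v_t * p.s_ext / (p.K_t + p.s_ext)
    return np.array(
        [
            g_a * c_tot / (p.M * lam) - 1.0,
            (g_a * c["r"] / (p.n_r * lam) - c_tot) / r - 1.0,
            prot["q"] / p_q - 1.0,
            p.n_s * v_cat / (lam * (p.M + a)) - 1.0,
            v_imp / (v_cat + lam * s_i) - 1.0,
        ]
    )


def _full_state_from_reduced(u: np.ndarray, p: WeisseParams) -> np.ndarray:
    a, r, lam, s_i, p_q, g_a, omega, c, m, prot = _reduced_state(u, p)
    return np.array(
        [
            s_i, a, r,
            m["r"], m["t"], m["m"], m["q"],
            c["r"], c["t"], c["m"], c["q"],
            prot["t"], prot["m"], prot["q"],
        ]
    )


def _reduced_guess_from_state(y: np.ndarray, p: WeisseParams) -> np.ndarray:
    lam = max(growth_rate_of_state(y, p), 1e-12)
    vals = np.array([y[1], y[2], lam, y[0], y[13]], dtype=float)
    return np.log(np.maximum(vals, 1e-12))


@dataclass
class SteadyState:
    """A converged steady state: growth rate, full state, provenance."""

    rate: float
    state: np.ndarray
    solver: str
    residual: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.state, index=list(SPECIES))


def _scaled_residual(y: np.ndarray, lam: float, p: WeisseParams) -> float:
    """max_i |dy_i| / (lambda * (|y_i| + 1)) — dimensionless closeness to
    steady state."""
    dy = _derivatives_clipped(y, p)
    return float(np.max(np.abs(dy) / (max(lam, 1e-12) * (np.abs(y) + 1.0))))


def _integrate(
    p: WeisseParams,
    y0: np.ndarray,
    horizon: float,
    rtol: float,
    drift_tol: float,
    max_doublings: int = 3,
):
    """Integrate until the relative change of lambda over the last 10% of
    the horizon drops below ``drift_tol``; double the horizon on failure."""
    t_final = horizon
    last = None
    for attempt in range(max_doublings + 1):
        sol = solve_ivp(
            lambda t, y: _derivatives_clipped(y, p),
            (0.0, t_final),
            y0,
            method="LSODA",
            t_eval=[0.9 * t_final, t_final],
            rtol=rtol,
            atol=1e-8,
        )
        if not sol.success:
            raise ConvergenceError(f"integration failed at t_final={t_final}: {sol.message}")
        y_win, y_end = sol.y[:, 0], sol.y[:, 1]
        lam_win = growth_rate_of_state(y_win, p)
        lam_end = growth_rate_of_state(y_end, p)
        drift = abs(lam_end - lam_win) / max(abs(lam_end), 1e-300)
        last = (t_final, lam_end, drift)
        if drift < drift_tol and lam_end > 0:
            return y_end, lam_end, drift
        y0 = y_end
        t_final *= 2.0
    raise ConvergenceError(
        "steady state not reached: horizon={:.3g} min, lambda={:.6g}/min, "
        "relative drift={:.3g} (tolerance {:.1g})".format(*last, drift_tol)
    )


def _root_continuation(
    target: WeisseParams,
    ref: WeisseParams,
    state_ref: np.ndarray,
    min_step: float = 1.0 / 64,
) -> Optional[SteadyState]:
    """Walk from ``ref`` to ``target`` along a log-linear homotopy in
    parameter space, root-solving at each step with the previous solution
    as warm start.  Handles severe mutations (steady-state growth orders
    of magnitude below the reference) without any integration."""
    names = [f.name for f in dataclasses.fields(WeisseParams)]
    lo = np.array([getattr(ref, f) for f in names])
    hi = np.array([getattr(target, f) for f in names])
    ratio = hi / lo
    s, step = 0.0, 0.5
    cur_state = state_ref
    result: Optional[SteadyState] = None
    while s < 1.0:
        step = min(step, 1.0 - s)
        s_try = s + step
        if s_try >= 1.0 - 1e-12:
            p_try = target
            s_try = 1.0
        else:
            p_try = WeisseParams(**dict(zip(names, lo * ratio**s_try)))
        cand = _try_root(p_try, cur_state)
        if cand is not None:
            s, cur_state, result = s_try, cand.state, cand
            step *= 2.0
        else:
            step /= 2.0
            if step < min_step:
                return None
    return result


def steady_state_growth(
    params: WeisseParams,
    solver: str = "auto",
    guess: Optional[Union[SteadyState, np.ndarray]] = None,
    ref_params: Optional[WeisseParams] = None,
    horizon: float = 1e4,
    drift_tol: float = 1e-8,
) -> SteadyState:
    """Steady-state growth rate of the model.

    solver:
      * ``"integrate"`` — stiff integration from a standard seed state
        until the relative drift of lambda over the last 10% of the horizon
        is below ``drift_tol`` (horizon doubles on failure, at most 3
        times);
      * ``"root"`` — coarse integration for an initial guess, then the
        reduced algebraic system solved to machine precision;
      * ``"auto"`` — like ``"root"``, but accepts a warm-start ``guess``
        (a previous :class:`SteadyState` or full state vector) and skips
        the integration when the root solve from the guess verifies; if
        ``ref_params`` (the parameter set the guess was solved under) is
        also given, a failed direct solve falls back to parameter-space
        continuation before resorting to integration.

    The returned ``residual`` is the scaled magnitude of the *full* system
    derivative at the reported state, so the reduced route is always
    verified against the complete ODE system.
    """
    if solver not in ("auto", "root", "integrate"):
        raise ValueError("solver must be 'auto', 'root', or 'integrate'")

    if solver == "integrate":
        y0 = default_initial_state(params) if guess is None else _as_state(guess)
        y_end, lam, drift = _integrate(params, y0, horizon, rtol=1e-10, drift_tol=drift_tol)
        return SteadyState(rate=lam, state=y_end, solver="integrate",
                           residual=_scaled_residual(y_end, lam, params))

    if solver == "auto" and guess is not None:
        ss = _try_root(params, _as_state(guess))
        if ss is not None:
            return ss
        if ref_params is not None:
            ss = _root_continuation(params, ref_params, _as_state(guess))
            if ss is not None:
                return ss
    # coarse integration then polish
    y0 = default_initial_state(params)
    y_end, lam, _ = _integrate(params, y0, horizon, rtol=1e-6, drift_tol=1e-5)
    ss = _try_root(params, y_end)
    if ss is not None:
        return ss
    # higher-accuracy integration as a last resort
    y_end, lam, _ = _integrate(params, y_end, horizon, rtol=1e-10, drift_tol=drift_tol)
    ss = _try_root(params, y_end)
    if ss is not None:
        return ss
    raise ConvergenceError(
        f"root polish failed after integration (lambda~{lam:.4g}/min)"
    )


def _as_state(guess: Union[SteadyState, np.ndarray]) -> np.ndarray:
    return guess.state if isinstance(guess, SteadyState) else np.asarray(guess, dtype=float)


def _try_root(params: WeisseParams, y_guess: np.ndarray) -> Optional[SteadyState]:
    u0 = _reduced_guess_from_state(y_guess, params)
    sol = scipy_root(_reduced_residuals, u0, args=(params,), method="hybr",
                     options={"xtol": 1e-13})
    if not sol.success and np.max(np.abs(_reduced_residuals(sol.x, params))) > 1e-9:
        return None
    y = _full_state_from_reduced(sol.x, params)
    lam = float(np.exp(np.clip(sol.x[2], -60, 60)))
    if lam <= 1e-10 or np.any(~np.isfinite(y)) or np.any(y < 0):
        return None
    resid = _scaled_residual(y, lam, params)
    if resid > 1e-6:
        return None
    return SteadyState(rate=lam, state=y, solver="root", residual=resid)


# ---------------------------------------------------------------------------
# Mutational scans
# ---------------------------------------------------------------------------

@dataclass
class PairScanResult:
    """Sampled double mutants for one parameter pair plus per-law mean
    deviations (absolute deviation is the headline; the signed mean is kept
    alongside)."""

    pair: Tuple[str, str]
    table: pd.DataFrame
    mean_abs_dev: Dict[str, float]
    mean_dev: Dict[str, float]
    wt_rate: float
    n_requested: int
    n_failed: int
    n_discarded_beneficial: int


def cross_process_pairs() -> List[Tuple[str, str]]:
    """All unordered mutable-parameter pairs whose processes differ."""
    return [
        (a, b)
        for a, b in itertools.combinations(sorted(MUTABLE_PARAMS), 2)
        if MUTABLE_PARAMS[a][0] != MUTABLE_PARAMS[b][0]
    ]


def pair_scan(
    pair: Tuple[str, str],
    n: int,
    seed: Optional[int] = None,
    params: Optional[WeisseParams] = None,
    wt: Optional[SteadyState] = None,
) -> PairScanResult:
    """Sample ``n`` double mutants for a cross-process parameter pair.

    Each sample draws independent ``theta ~ U(0, 1]`` for the two
    parameters, computes the two single-mutant and the double-mutant
    steady-state growth rates, and records fitnesses relative to wild
    type.  Samples whose steady state cannot be computed are dropped and
    counted (``n_failed``); samples where a nominally deleterious mutation
    increased growth are discarded and counted
    (``n_discarded_beneficial``).
    """
    alpha, beta = pair
    for name in (alpha, beta):
        if name not in MUTABLE_PARAMS:
            raise ValueError(f"unknown mutable parameter {name!r}")
    if MUTABLE_PARAMS[alpha][0] == MUTABLE_PARAMS[beta][0]:
        raise ValueError(
            f"parameters {alpha!r} and {beta!r} belong to the same process "
            f"({MUTABLE_PARAMS[alpha][0]}); only cross-process pairs are scanned"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params if params is not None else WeisseParams.default()
    if wt is None:
        wt = steady_state_growth(p)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    n_beneficial = 0
    tol = 1e-6
    for _ in range(n):
        th_a = 1.0 - rng.random()
        th_b = 1.0 - rng.random()
        p_x = mutate(p, alpha, th_a)
        p_y = mutate(p, beta, th_b)
        try:
            ss_x = steady_state_growth(p_x, guess=wt, ref_params=p)
            ss_y = steady_state_growth(p_y, guess=wt, ref_params=p)
            if ss_x.rate <= ss_y.rate:
                guess_xy, ref_xy = ss_x, p_x
            else:
                guess_xy, ref_xy = ss_y, p_y
            ss_xy = steady_state_growth(
                mutate(p_x, beta, th_b), guess=guess_xy, ref_params=ref_xy
            )
        except ConvergenceError:
            n_failed += 1
            continue
        w_x = ss_x.rate / wt.rate
        w_y = ss_y.rate / wt.rate
        w_xy = ss_xy.rate / wt.rate
        if w_x > 1 + tol or w_y > 1 + tol:
            n_beneficial += 1
            continue
        rows.append((th_a, th_b, min(w_x, 1.0), min(w_y, 1.0), w_xy))
    table = pd.DataFrame(
        rows, columns=["theta_x", "theta_y", "w_x", "w_y", "w_xy"]
    )
    mean_abs: Dict[str, float] = {}
    mean_signed: Dict[str, float] = {}
    for law in LAWS:
        pred = predict(law, table["w_x"].to_numpy(), table["w_y"].to_numpy())
        dev = table["w_xy"].to_numpy() - pred
        mean_abs[law] = float(np.mean(np.abs(dev))) if len(dev) else float("nan")
        mean_signed[law] = float(np.mean(dev)) if len(dev) else float("nan")
    if n_failed:
        logger.warning("pair %s: %d/%d samples failed to converge", pair, n_failed, n)
    return PairScanResult(
        pair=pair,
        table=table,
        mean_abs_dev=mean_abs,
        mean_dev=mean_signed,
        wt_rate=wt.rate,
        n_requested=n,
        n_failed=n_failed,
        n_discarded_beneficial=n_beneficial,
    )


def deviation_matrix(
    n: int,
    seed: Optional[int] = None,
    params: Optional[WeisseParams] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Mean |deviation| from each law for every cross-process pair.

    One row per pair with columns ``param_a, param_b, process_a, process_b,
    involves_translation, n_effective`` and one ``dev_<law>`` column per
    law — the matrix behind the pair-by-law heat map.
    """
    p = params if params is not None else WeisseParams.default()
    wt = steady_state_growth(p)
    pairs = list(pairs) if pairs is not None else cross_process_pairs()
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for pair, ss in zip(pairs, seeds):
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        res = pair_scan(pair, n=n, seed=child_seed, params=p, wt=wt)
        proc_a, proc_b = MUTABLE_PARAMS[pair[0]][0], MUTABLE_PARAMS[pair[1]][0]
        row = {
            "param_a": pair[0],
            "param_b": pair[1],
            "process_a": proc_a,
            "process_b": proc_b,
            "involves_translation": "translation" in (proc_a, proc_b),
            "n_effective": len(res.table),
        }
        row.update({f"dev_{law}": res.mean_abs_dev[law] for law in LAWS})
        rows.append(row)
    return pd.DataFrame(rows)


def gamma_sweep(
    gamma_values: Sequence[float],
    pair: Tuple[str, str] = ("v_t", "n_s"),
    n: int = 200,
    seed: Optional[int] = None,
    params: Optional[WeisseParams] = None,
) -> pd.DataFrame:
    """Median |Product residual| of a pair scan as a function of ``gamma``.

    For each gamma the transcription threshold is set to ``theta_x =
    1/gamma`` and the wild type is recomputed, so fitnesses are relative to
    the matched wild type.  The same seed is reused across gamma values
    (common random numbers), which removes sampling noise from the
    between-gamma comparison.
    """
    if any(g <= 0 for g in gamma_values):
        raise ValueError("gamma values must be positive")
    p = params if params is not None else WeisseParams.default()
    rows = []
    for gamma in gamma_values:
        pg = p.with_gamma(gamma)
        res = pair_scan(pair, n=n, seed=seed, params=pg)
        resid = res.table["w_xy"] - res.table["w_x"] * res.table["w_y"]
        rows.append(
            {
                "gamma": gamma,
                "theta_x": pg.theta_x,
                "median_abs_product_residual": float(np.median(np.abs(resid))),
                "mean_abs_product_residual": float(np.mean(np.abs(resid))),
                "wt_rate": res.wt_rate,
                "n_effective": len(res.table),
            }
        )
    return pd.DataFrame(rows)
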