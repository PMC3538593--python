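"""Composite likelihood ratio (CLR) sweep scan and goodness-of-fit test.

The sweep model is a star-like instantaneous hitchhiking approximation: a
beneficial allele of population-scaled strength alpha = 2Ns fixed at map
position X. A neutral lineage at recombination distance d escapes the sweep
with probability

    p_esc(d) = 1 - epsilon**(rho d / alpha),

where rho is the per-site population recombination rate (2N units) and
epsilon (default 1e-6, roughly 1/2N for a large Drosophila population) sets
the sweep's time scale. Conditional on B ~ Binomial(n, p_esc) escapees, the
pre-sweep genealogy is a neutral coalescent of B + 1 lineages (all swept
lineages collapse into one ancestor), which yields a closed-form expected
unfolded frequency spectrum phi(k | p_esc) and an expected relative
polymorphism retention lambda(p_esc).

The scan ("test B" flavor: the level of variation enters through theta_W
estimated from the data, with an outgroup polarizing the spectrum) maximizes
the composite log likelihood over an (alpha, X) lattice:

    ln L(alpha, X) = sum_seg [ln q_i + ln phi(k_i | p_esc(d_i))]
                   + sum_mono ln(1 - q_i),
    q_i = min(1, theta_W a_n lambda(p_esc(d_i))),

against the neutral model (p_esc == 1 everywhere). Significance comes from
empirical max-Lambda null distributions simulated with `sweepkit.coalsim`.

The GOF follow-up compares the fitted sweep model to a saturated alternative
in which each site's derived count is binomially distributed with its own
free frequency; its null distribution is built by re-fitting data simulated
under the fitted sweep model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from sweepkit._util import harmonic
from sweepkit.coalsim import (
    DemographyModel,
    SimulationConfig,
    simulate_fixed_S,
    simulate_neutral,
    simulate_sweep,
)

_LOG_FLOOR = -700.0  # ln of the smallest useful double


class InsufficientDataError(ValueError):
    """Fewer polarized segregating sites than the scan requires."""


def escape_probability(d, rho_per_site: float, alpha: float, epsilon: float = 1e-6):
    """Probability that a lineage at distance d (bp) escapes the sweep.

    p_esc = 1 - epsilon**(rho d / alpha), clipped to [0, 1). Accepts scalar
    or array d.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if epsilon <= 0 or epsilon >= 1:
        raise ValueError("epsilon must lie in (0, 1)")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    r = rho_per_site * d / alpha
    p = -np.expm1(r * np.log(epsilon))
    p = np.clip(p, 0.0, 1.0 - 1e-12)
    return float(p) if p.ndim == 0 else p


def _sweep_weights(n: int, p_esc: float) -> np.ndarray:
    """Unnormalized expected SFS weights under the post-sweep mixture.

    Mixes over B ~ Binomial(n, p_esc) escaped lineages: given B = b < n the
    pre-sweep sample behaves as a neutral coalescent of m = b + 1 lineages
    (expected length of branches with j descendants: 1/j); a mutation of
    multiplicity j maps to full-sample derived count j - 1 + (n - b) when the
    collapsed lineage is a carrier (probability j/m) and j otherwise.
    """
    w = np.zeros(n - 1)
    bprob = stats.binom.pmf(np.arange(n + 1), n, p_esc)
    # b = n: nothing swept, plain neutral spectrum
    ks = np.arange(1, n)
    w += bprob[n] / ks
    for b in range(1, n):
        m = b + 1
        for j in range(1, m):
            lj = 1.0 / j
            k_hit = j - 1 + (n - b)
            if 1 <= k_hit <= n - 1:
                w[k_hit - 1] += bprob[b] * lj * (j / m)
            w[j - 1] += bprob[b] * lj * ((m - j) / m)
    return w


def sweep_sfs(n: int, p_esc: float) -> np.ndarray:
    """phi(k | p_esc): normalized post-sweep derived-count distribution.

    Returns a length n-1 probability vector over k = 1..n-1. For p_esc = 0
    (complete sweep) there is no segregating mass and the zero vector is
    returned as the monomorphic indicator.
    """
    if not (0.0 <= p_esc <= 1.0):
        raise ValueError("p_esc must be in [0, 1]")
    w = _sweep_weights(n, p_esc)
    tot = w.sum()
    if tot <= 0:
        return w
    return w / tot


def lambda_retention(n: int, p_esc) -> np.ndarray:
    """Expected relative polymorphism retention lambda(p_esc) in [0, 1].

    lambda = E[a_{B+1}] / a_n with B ~ Binomial(n, p_esc) (a_1 = 0; B = n
    keeps the full neutral tree). Accepts scalar or array p_esc.
    """
    p = np.atleast_1d(np.asarray(p_esc, dtype=float))
    a = np.array([harmonic(m) for m in range(0, n + 2)])  # a[m] = a_m
    bvals = np.arange(n + 1)
    am = np.where(bvals < n, a[np.minimum(bvals + 1, n)], a[n])
    out = np.empty_like(p)
    for i, pi in enumerate(p):
        bprob = stats.binom.pmf(bvals, n, pi)
        out[i] = float(np.sum(bprob * am) / a[n])
    return float(out[0]) if np.isscalar(p_esc) or np.ndim(p_esc) == 0 else out


# cached (pgrid, lambda grid, ln-phi grid) per sample size
_MODEL_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
_GRID_SIZE = 513


def _model_tables(n: int):
    if n not in _MODEL_CACHE:
        pgrid = np.linspace(0.0, 1.0, _GRID_SIZE)
        lam = lambda_retention(n, pgrid)
        lnphi = np.full((n - 1, _GRID_SIZE), _LOG_FLOOR)
        for gi, p in enumerate(pgrid):
            phi = sweep_sfs(n, float(p))
            pos = phi > 0
            lnphi[pos, gi] = np.log(phi[pos])
        _MODEL_CACHE[n] = (pgrid, lam, lnphi)
    return _MODEL_CACHE[n]


def _interp_columns(table: np.ndarray, rows: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Linear interpolation of table[rows, .] at fractional grid positions p."""
    G = table.shape[1]
    x = np.clip(p, 0.0, 1.0) * (G - 1)
    lo = np.minimum(x.astype(int), G - 2)
    frac = x - lo
    return table[rows, lo] * (1.0 - frac) + table[rows, lo + 1] * frac


@dataclass
class SweepModelFit:
    """Maximum composite-likelihood sweep fit for one region."""

    alpha_hat: float  # 2Ns units; 0 means the neutral model was not beaten
    x_hat: float  # alignment position (bp); nan when alpha_hat == 0
    clr: float  # Lambda = 2 (ln L_sweep - ln L_neutral) >= 0
    lnL_sweep: float
    lnL_neutral: float
    n: int
    L: int
    S: int
    theta_w: float
    rho_per_site: float
    epsilon: float
    p_snm: Optional[object] = None
    p_bottleneck: Optional[object] = None
    surface: Optional[np.ndarray] = None  # (alpha, X, lnL) rows if requested


def clr_scan(
    positions,
    counts,
    n: int,
    L: int,
    theta_w: float,
    rho_per_site: float,
    grid_alphas: Optional[np.ndarray] = None,
    x_step: int = 100,
    epsilon: float = 1e-6,
    keep_surface: bool = False,
) -> SweepModelFit:
    """Composite likelihood ratio scan over an (alpha, X) lattice.

    positions/counts: outgroup-polarized biallelic segregating sites (bp
    position in [0, L), derived count in 1..n-1). theta_w is the per-site
    Watterson estimate entering both models. The alpha grid defaults to 50
    log-spaced points on [10, 1e5]; X candidates are every x_step bp plus
    every segregating-site position. Ties break toward smaller alpha, then
    smaller X; the neutral model is always a candidate, so Lambda >= 0.
    """
    positions = np.asarray(positions, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if len(positions) != len(counts):
        raise ValueError("positions and counts differ in length")
    keep = (counts >= 1) & (counts <= n - 1)
    positions, counts = positions[keep], counts[keep]
    S = len(positions)
    if S < 2:
        raise InsufficientDataError(
            f"{S} polarized segregating site(s); the scan needs at least 2"
        )
    if not ((positions >= 0) & (positions < L)).all():
        raise ValueError("site positions must lie in [0, L)")
    a_n = harmonic(n)
    _, lam_grid, lnphi_grid = _model_tables(n)

    q_cap = 1.0 - 1e-9
    q0 = min(theta_w * a_n, q_cap)
    ln_phi0 = np.log(1.0 / counts / a_n)
    lnL0 = float(S * np.log(q0) + ln_phi0.sum() + (L - S) * np.log1p(-q0))

    if grid_alphas is None:
        grid_alphas = np.geomspace(10.0, 1e5, 50)
    xs = np.unique(
        np.concatenate(
            [np.arange(0, L, x_step, dtype=int), np.round(positions).astype(int)]
        )
    )
    xs = xs[(xs >= 0) & (xs < L)]

    best_lnl = lnL0
    best_alpha = 0.0
    best_x = np.nan
    d_all = np.arange(L, dtype=float)
    surface = [] if keep_surface else None

    for alpha in grid_alphas:
        # per-distance monomorphic factor, shared across X via prefix sums
        p_d = escape_probability(d_all, rho_per_site, float(alpha), epsilon)
        lam_d = np.interp(p_d, *_pgrid_pair(n, lam_grid))
        q_d = np.minimum(theta_w * a_n * lam_d, q_cap)
        A = np.log1p(-q_d)
        P = np.cumsum(A)
        mono_all = P[xs] + P[L - 1 - xs] - A[0]

        D = np.abs(positions[:, None] - xs[None, :])
        p_seg = escape_probability(D, rho_per_site, float(alpha), epsilon)
        lam_seg = np.interp(p_seg.ravel(), *_pgrid_pair(n, lam_grid)).reshape(p_seg.shape)
        q_seg = np.minimum(theta_w * a_n * lam_seg, q_cap)
        with np.errstate(divide="ignore"):
            ln_q_seg = np.log(q_seg)
        ln_phi_seg = _interp_columns(lnphi_grid, counts[:, None] - 1, p_seg)
        seg_term = (ln_q_seg + ln_phi_seg).sum(axis=0)
        mono_term = mono_all - np.log1p(-q_seg).sum(axis=0)
        lnl_x = seg_term + mono_term
        if keep_surface:
            surface.append(np.column_stack([np.full(len(xs), alpha), xs, lnl_x]))
        i = int(np.argmax(lnl_x))
        if lnl_x[i] > best_lnl:
            best_lnl = float(lnl_x[i])
            best_alpha = float(alpha)
            best_x = float(xs[i])

    return SweepModelFit(
        alpha_hat=best_alpha,
        x_hat=best_x,
        clr=2.0 * (best_lnl - lnL0),
        lnL_sweep=best_lnl,
        lnL_neutral=lnL0,
        n=n,
        L=L,
        S=S,
        theta_w=theta_w,
        rho_per_site=rho_per_site,
        epsilon=epsilon,
        surface=np.vstack(surface) if keep_surface else None,
    )


def _pgrid_pair(n, lam_grid):
    pgrid, _, _ = _model_tables(n)
    return pgrid, lam_grid


def clr_null_distribution(
    n: int,
    L: int,
    rho_per_site: float,
    reps: int,
    seed: Optional[int] = None,
    theta: Optional[float] = None,
    theta_prior: Optional[tuple[float, float]] = None,
    fixed_S: Optional[int] = None,
    demography: Optional[DemographyModel] = None,
    grid_alphas: Optional[np.ndarray] = None,
    x_step: int = 100,
    epsilon: float = 1e-6,
    n_windows: Optional[int] = None,
) -> np.ndarray:
    """Null distribution of the max CLR statistic under neutrality.

    Simulates `reps` neutral datasets (plain at theta, or fixed-S with a
    theta prior) at matched n, L, rho and demography, re-estimates theta_W
    from each dataset, and re-runs the scan. Replicates with fewer than two
    segregating sites score Lambda = 0 (the scan cannot beat neutrality).
    """
    cfg = SimulationConfig(
        n=n,
        L=L,
        theta=theta,
        theta_prior=theta_prior,
        fixed_S=fixed_S,
        rho_per_site=rho_per_site,
        reps=reps,
        seed=seed,
        n_windows=n_windows,
    )
    if fixed_S is not None:
        reps_set = simulate_fixed_S(cfg, demography)
    else:
        reps_set = simulate_neutral(cfg, demography)
    a_n = harmonic(n)
    lam = np.zeros(reps)
    for r in range(reps):
        pos, cnt = reps_set.positions[r], reps_set.counts[r]
        S_r = len(pos)
        if S_r < 2:
            continue
        theta_w = S_r / (a_n * L)
        fit = clr_scan(
            pos, cnt, n, L, theta_w, rho_per_site,
            grid_alphas=grid_alphas, x_step=x_step, epsilon=epsilon,
        )
        lam[r] = fit.clr
    return lam


@dataclass
class GOFResult:
    """Goodness-of-fit of the fitted sweep model vs the saturated alternative."""

    gof_stat: float
    p_value: float
    reps: int
    seed: Optional[int]
    null_stats: np.ndarray = field(repr=False, default=None)
    low_resolution: bool = False


def _general_lnl(counts: np.ndarray, n: int) -> float:
    """Saturated model: each site's derived count Binomial(n, k_i/n)."""
    k = np.asarray(counts, dtype=float)
    return float(np.sum(stats.binom.logpmf(k, n, k / n)))


def gof_stat(fit: SweepModelFit, counts) -> float:
    """2 (ln L_general - ln L_sweep) for the fitted sweep model."""
    return 2.0 * (_general_lnl(np.asarray(counts), fit.n) - fit.lnL_sweep)


def gof_test(
    fit: SweepModelFit,
    positions,
    counts,
    reps: int = 1000,
    seed: Optional[int] = None,
    demography: Optional[DemographyModel] = None,
    time_since_sweep: float = 0.0,
    grid_alphas: Optional[np.ndarray] = None,
    x_step: int = 100,
    n_windows: Optional[int] = None,
) -> GOFResult:
    """GOF test: is the fitted sweep model an adequate description?

    The statistic is 2(lnL_general - lnL_sweep) with the saturated per-site
    binomial alternative. The null distribution re-simulates data under the
    fitted sweep model (theta = the observed theta_W per site), re-fits the
    scan, and re-scores; p = fraction of null statistics >= observed. Large
    p (sweep not rejected) supports the sweep interpretation.
    """
    if fit.alpha_hat <= 0:
        raise ValueError("GOF requires a fitted sweep model (alpha_hat > 0)")
    obs = gof_stat(fit, counts)
    rng = np.random.default_rng(seed)
    null = []
    attempts = 0
    a_n = harmonic(fit.n)
    while len(null) < reps and attempts < 10 * reps:
        attempts += 1
        cfg = SimulationConfig(
            n=fit.n, L=fit.L, theta=fit.theta_w,
            rho_per_site=fit.rho_per_site, reps=1, n_windows=n_windows,
        )
        sim = simulate_sweep(
            cfg,
            alpha=fit.alpha_hat,
            X=fit.x_hat,
            time_since_sweep=time_since_sweep,
            epsilon=fit.epsilon,
            demography=demography,
            rng=rng,
        )
        pos, cnt = sim.positions[0], sim.counts[0]
        if len(pos) < 2:
            continue
        theta_w = len(pos) / (a_n * fit.L)
        try:
            refit = clr_scan(
                pos, cnt, fit.n, fit.L, theta_w, fit.rho_per_site,
                grid_alphas=grid_alphas, x_step=x_step, epsilon=fit.epsilon,
            )
        except InsufficientDataError:
            continue
        null.append(2.0 * (_general_lnl(cnt, fit.n) - refit.lnL_sweep))
    null = np.asarray(null)
    if len(null) == 0:
        raise RuntimeError("no usable GOF null replicates (all monomorphic)")
    p = float(np.mean(null >= obs))
    return GOFResult(
        gof_stat=float(obs),
        p_value=p,
        reps=len(null),
        seed=seed,
        null_stats=null,
        low_resolution=len(null) < 100,
    )
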