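"""Analytic predictions for allele-frequency dynamics under stabilizing selection.

A locus with additive effect ``a`` on a trait under Gaussian stabilizing
selection (peak width ``w``) experiences, when the population mean sits at
the optimum, an effectively underdominant selection regime: writing
``c = a**2 / (2 * (w**2 + V_P))``, the deterministic per-generation change
in the derived-allele frequency is

    dp = c * p * q * (2 p - 1) / (1 - 2 c p q),

so ``p = 1/2`` is an unstable equilibrium and the minor allele is driven
out.  The population-scaled strength of this process is
``S = 2 N a**2 / w**2``; heterozygosity (and hence the genic variance
``2 p q a**2`` contributed by the locus) decays faster than the neutral
``(1 - 1/2N)**t``.

Three mutually checking routes to the retention of ancestral variance are
implemented:

* ``closed_form_retention`` -- cheap textbook approximations treating the
  per-generation selective loss as frequency-independent,
* ``wf_matrix_retention`` -- brute-force iteration of the full
  Wright-Fisher transition matrix at small N,
* ``diffusion_retention`` -- Crank-Nicolson integration of the backward
  Kolmogorov equation of the underdominant diffusion, started from the
  mutation-selection-drift stationary density.

The diffusion route also yields the equilibrium density of variance by
effect size, the fraction of ancestral variance remaining after ``t``
generations, and the expected relative accuracy in an unrepresented
population of a polygenic score ascertained in a represented one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded
from scipy.stats import binom

from .config import TheoryConfig, EffectDistribution

__all__ = [
    "scaled_selection",
    "closed_form_retention",
    "deterministic_trajectory",
    "wf_matrix_retention",
    "wf_stationary_counts",
    "diffusion_retention",
    "equilibrium_variance_density",
    "ancestral_variance_remaining",
    "shared_variance_ratio",
    "top_variance_share",
    "sojourn_density",
    "sample_equilibrium_loci",
]


# ----------------------------------------------------------------------
# elementary quantities
# ----------------------------------------------------------------------

def scaled_selection(a: float | np.ndarray, N: int, w: float) -> float | np.ndarray:
    """Population-scaled selection coefficient ``S = 2 N a^2 / w^2``."""
    if not w > 0:
        raise ValueError("w must be positive")
    return 2.0 * N * np.asarray(a, dtype=float) ** 2 / w**2


def _sel_coeff(a: float, w: float, V_P: float = 0.0) -> float:
    """Per-generation underdominant coefficient ``c = a^2 / (2 (w^2 + V_P))``."""
    return a * a / (2.0 * (w * w + V_P))


@dataclass(frozen=True)
class RetentionClosedForm:
    """Both textbook forms of the ancestral-variance retention fraction."""

    product: float      # (1 - 1/2N)^t (1 - a^2 / (4 (w^2 + V_P)))^t
    exponential: float  # exp(-F_ST (1 + S/4)),  F_ST = t / 2N


def closed_form_retention(a: float, t: float, N: int, w: float,
                          V_P: float = 0.0) -> RetentionClosedForm:
    """Frequency-independent approximations to heterozygosity retention.

    The product form compounds the per-generation drift loss ``1/2N`` and
    the selective loss ``a^2 / (4 (w^2 + V_P))``; the exponential form is
    its first-order equivalent ``exp(-F_ST (1 + S/4))`` with
    ``F_ST = t/2N``.  Both ignore the dependence of the selective loss on
    the current allele frequency, which the diffusion accounts for.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if V_P < 0:
        raise ValueError("V_P must be >= 0")
    sel_loss = a * a / (4.0 * (w * w + V_P))
    if sel_loss >= 1.0:
        raise ValueError(
            f"per-generation selective loss {sel_loss:.3f} >= 1: outside the "
            "weak-selection domain of this approximation")
    product = (1.0 - 1.0 / (2 * N)) ** t * (1.0 - sel_loss) ** t
    fst = t / (2.0 * N)
    S = scaled_selection(a, N, w)
    exponential = math.exp(-fst * (1.0 + S / 4.0))
    return RetentionClosedForm(product=product, exponential=exponential)


def deterministic_trajectory(p0: float, a: float, w: float, generations: int,
                             V_P: float = 0.0) -> np.ndarray:
    """Infinite-population underdominant frequency path from ``p0``.

    ``p = 1/2`` is an unstable fixed point; trajectories starting the same
    distance from their nearest boundary are mirror images, and larger
    effects reach the boundary faster.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    c = _sel_coeff(a, w, V_P)
    path = np.empty(generations + 1)
    p = p0
    path[0] = p
    for g in range(1, generations + 1):
        pq = p * (1.0 - p)
        p = (p - c * pq) / (1.0 - 2.0 * c * pq)
        path[g] = p
    return path


# ----------------------------------------------------------------------
# Wright-Fisher transition-matrix oracle
# ----------------------------------------------------------------------

_WF_N_MAX = 500


def _wf_transition(N: int, a: float, w: float | None,
                   V_P: float = 0.0) -> np.ndarray:
    """Interior-to-all transition matrix of the WF chain with underdominance.

    Row ``i`` (count ``i`` of ``2N`` copies, ``1 <= i <= 2N-1``) is the
    Binomial(2N, p*) distribution where ``p*`` applies the deterministic
    underdominant change to ``p = i / 2N``.
    """
    if N > _WF_N_MAX:
        raise ValueError(f"transition matrix requested for N={N} > {_WF_N_MAX}")
    i = np.arange(1, 2 * N)
    p = i / (2.0 * N)
    if w is None or math.isinf(w):
        pstar = p
    else:
        c = _sel_coeff(a, w, V_P)
        pq = p * (1.0 - p)
        pstar = (p - c * pq) / (1.0 - 2.0 * c * pq)
    pstar = np.clip(pstar, 0.0, 1.0)
    j = np.arange(0, 2 * N + 1)
    return binom.pmf(j[None, :], 2 * N, pstar[:, None])


def wf_stationary_counts(N: int, a: float, w: float | None,
                         V_P: float = 0.0) -> np.ndarray:
    """Stationary density of segregating copy-counts under unit influx.

    Solves ``n = n T + e_1`` where new mutations enter at count 1; the
    result is the expected number of segregating loci per unit mutational
    influx at each count ``1..2N-1`` (finite-population analogue of the
    diffusion sojourn density).
    """
    T = _wf_transition(N, a, w, V_P)[:, 1:2 * N]
    e1 = np.zeros(2 * N - 1)
    e1[0] = 1.0
    n = np.linalg.solve(np.eye(2 * N - 1) - T.T, e1)
    return n


def wf_matrix_retention(a: float, t: int, N_small: int, w: float | None,
                        V_P: float = 0.0,
                        start: str | float = "stationary") -> float:
    """Expected retained heterozygosity fraction from the full WF matrix.

    ``start`` is either ``"stationary"`` (mutation-selection-drift
    stationary density over segregating counts) or a float frequency at
    which all mass begins.  With selection off this reproduces
    ``(1 - 1/2N)**t`` exactly for any start.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    T = _wf_transition(N_small, a, w, V_P)[:, 1:2 * N_small]
    if start == "stationary":
        f = wf_stationary_counts(N_small, a, w, V_P)
    else:
        f = np.zeros(2 * N_small - 1)
        idx = int(round(float(start) * 2 * N_small)) - 1
        f[min(max(idx, 0), 2 * N_small - 2)] = 1.0
    p = np.arange(1, 2 * N_small) / (2.0 * N_small)
    h = 2.0 * p * (1.0 - p)
    h0 = float(f @ h)
    for _ in range(int(t)):
        f = f @ T
    return float(f @ h) / h0


# ----------------------------------------------------------------------
# diffusion machinery
# ----------------------------------------------------------------------

def _freq_grid(n: int) -> np.ndarray:
    """Chebyshev-extrema grid on (0, 1): dense near the absorbing boundaries."""
    j = np.arange(0, n + 1)
    return (1.0 - np.cos(np.pi * j / n)) / 2.0


#: Alleles with S beyond this cap contribute negligibly to the variance;
#: capping keeps exp(S x (1-x)) within double range.
_S_CAP = 700.0


def sojourn_density(S: float, N: int, x: np.ndarray) -> np.ndarray:
    """Expected generations spent at frequency ``x`` by a new mutation.

    Standard diffusion sojourn density for entry at ``p0 = 1/(2N)``, with
    scale density ``psi(x) = exp(S x (1 - x))`` (underdominance makes
    intermediate frequencies hard to reach).  In the neutral limit this is
    the classic ``2 / x``.
    """
    S = min(float(S), _S_CAP)
    x = np.asarray(x, dtype=float)
    p0 = 1.0 / (2.0 * N)
    psi = np.exp(S * x * (1.0 - x))
    # scale function Sc(x) = int_0^x psi on a fine internal grid
    xf = np.linspace(0.0, 1.0, 4001)
    psif = np.exp(S * xf * (1.0 - xf))
    Scf = np.concatenate([[0.0], cumulative_trapezoid(psif, xf)])
    Sc = np.interp(x, xf, Scf)
    Sc_tot = Scf[-1]
    Sc_p0 = np.interp(p0, xf, Scf)
    v = x * (1.0 - x)
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = 2.0 * Sc_p0 * (Sc_tot - Sc) / (v * psi * Sc_tot)
        lower = 2.0 * (Sc_tot - Sc_p0) * Sc / (v * psi * Sc_tot)
        t_tau = np.where(x >= p0, upper, lower)
    t_tau = np.where((x <= 0.0) | (x >= 1.0), 0.0, t_tau)
    return 2.0 * N * t_tau  # tau units -> generations


def _backward_operator(S: float, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal backward generator on interior nodes (tau = t/2N units).

    ``L g = m g' + (v/2) g''`` with ``m = (S/2) x(1-x)(2x-1)`` and
    ``v = x(1-x)``; absorbing boundaries (g = 0 at 0 and 1).
    Returns (sub, diag, super) of the interior operator.
    """
    xi = x[1:-1]
    hm = xi - x[:-2]
    hp = x[2:] - xi
    m = (S / 2.0) * xi * (1.0 - xi) * (2.0 * xi - 1.0)
    v2 = xi * (1.0 - xi) / 2.0
    # nonuniform central differences
    c_m = -m * hp / (hm * (hm + hp)) + v2 * 2.0 / (hm * (hm + hp))
    c_0 = m * (hp - hm) / (hm * hp) - v2 * 2.0 / (hm * hp)
    c_p = m * hm / (hp * (hm + hp)) + v2 * 2.0 / (hp * (hm + hp))
    return c_m, c_0, c_p


def _propagate_backward(S: float, x: np.ndarray, g0: np.ndarray,
                        taus: np.ndarray, dt: float = 1e-3) -> np.ndarray:
    """Crank-Nicolson integration of ``dg/dtau = L g`` from terminal data.

    Returns ``g(x_interior, tau)`` for each requested ``tau`` (shape
    ``(len(taus), len(x) - 2)``); ``g(x0, tau)`` is the expectation of the
    terminal functional after ``tau`` time units starting from ``x0``.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    order = np.argsort(taus)
    c_m, c_0, c_p = _backward_operator(S, x)
    n = len(c_0)
    out = np.empty((len(taus), n))
    g = g0.astype(float).copy()
    t_now = 0.0
    for k in order:
        target = taus[k]
        if target < t_now - 1e-12:
            raise ValueError("taus must be propagated forward")
        while t_now < target - 1e-12:
            step = min(dt, target - t_now)
            hb = step / 2.0
            # rhs = (I + hb L) g
            rhs = g + hb * (c_0 * g)
            rhs[1:] += hb * c_m[1:] * g[:-1]
            rhs[:-1] += hb * c_p[:-1] * g[1:]
            # solve (I - hb L) g_new = rhs
            ab = np.zeros((3, n))
            ab[0, 1:] = -hb * c_p[:-1]
            ab[1, :] = 1.0 - hb * c_0
            ab[2, :-1] = -hb * c_m[1:]
            g = solve_banded((1, 1), ab, rhs)
            t_now += step
        out[k] = g
    return out


def _interior_weights(x: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for the interior nodes of ``x``."""
    w = np.zeros(len(x))
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    # boundary mass is absorbed into the neighbours; integrands vanish there
    return w[1:-1]


def diffusion_retention(a: float, t: float | np.ndarray, N: int, w: float,
                        V_P: float = 0.0, n_freq: int = 400) -> np.ndarray | float:
    """Retention of ancestral heterozygosity from the underdominant diffusion.

    Starts from the mutation-selection-drift stationary density of
    segregating ancestral loci and returns
    ``E[2 p q]_t / E[2 p q]_0`` for each requested ``t`` (generations).
    """
    S = float(scaled_selection(a, N, w)) * w * w / (w * w + V_P)
    x = _freq_grid(n_freq)
    xi = x[1:-1]
    n0 = sojourn_density(S, N, xi)
    h = 2.0 * xi * (1.0 - xi)
    wq = _interior_weights(x)
    taus = np.atleast_1d(np.asarray(t, dtype=float)) / (2.0 * N)
    u_h = _propagate_backward(S, x, h, taus)
    denom = float(np.sum(wq * n0 * h))
    vals = (u_h * (wq * n0)).sum(axis=1) / denom
    return vals if np.ndim(t) else float(vals[0])


# ----------------------------------------------------------------------
# equilibrium variance density and its decay
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceDensity:
    """Equilibrium genic-variance density on an effect-size grid.

    ``density[i]`` is variance per unit (positive) effect size at
    ``effects[i]``; ``total`` is the integrated equilibrium genic
    variance; ``het_integral[i]`` is the expected heterozygosity-
    generations contributed by one mutation of that effect.
    """

    effects: np.ndarray
    density: np.ndarray
    het_integral: np.ndarray
    total: float


def _het_sojourn_integral(S: float, N: int, n_freq: int = 400) -> float:
    """``int 2x(1-x) t_gen(x) dx``: per-mutation heterozygosity-generations."""
    x = _freq_grid(n_freq)[1:-1]
    wq = _interior_weights(_freq_grid(n_freq))
    n0 = sojourn_density(S, N, x)
    return float(np.sum(wq * 2.0 * x * (1.0 - x) * n0))


def equilibrium_variance_density(cfg: TheoryConfig,
                                 _check_mass: bool = True) -> VarianceDensity:
    """Equilibrium density of genic variance contributed by each effect size.

    For each (folded, positive) effect ``a`` with mutational density
    ``2 mu(a)``, the stationary contribution is
    ``N U * 2 mu(a) * a^2 * int 2x(1-x) t(x; S(a)) dx``.
    Narrower fitness peaks (smaller ``w``) push the mass toward smaller
    effects because large-effect alleles are purged before they can drift
    to appreciable frequency.
    """
    scale = cfg.effect_scale
    a = cfg.effect_dist.quantile_grid(cfg.n_effect, scale=scale)
    mu2 = 2.0 * cfg.effect_dist.pdf(a, scale=scale)
    if cfg.neutral:
        hint = np.full_like(a, _het_sojourn_integral(0.0, cfg.N, cfg.n_freq))
    else:
        S = 2.0 * cfg.N * a**2 / (cfg.w**2 + cfg.V_P)
        hint = np.array([_het_sojourn_integral(s, cfg.N, cfg.n_freq) for s in S])
    dens = cfg.N * cfg.U * mu2 * a**2 * hint
    total = float(np.trapezoid(dens, a))
    if _check_mass:
        finer = TheoryConfig(N=cfg.N, w=cfg.w, U=cfg.U, V_P=cfg.V_P,
                             effect_dist=cfg.effect_dist,
                             scale_effects=cfg.scale_effects,
                             n_freq=cfg.n_freq, n_effect=2 * cfg.n_effect)
        total2 = equilibrium_variance_density(finer, _check_mass=False).total
        if abs(total2 - total) > 2e-3 * max(total2, 1e-300):
            raise ValueError(
                f"effect grid too coarse to conserve variance mass "
                f"({total:.6g} vs {total2:.6g} on refinement)")
    return VarianceDensity(effects=a, density=dens, het_integral=hint, total=total)


def ancestral_variance_remaining(cfg: TheoryConfig, t: float | np.ndarray,
                                 method: str = "diffusion") -> np.ndarray | float:
    """Fraction of the ancestral genic variance remaining after ``t`` generations.

    Integrates the per-effect retention ``R(a, t)`` against the
    equilibrium variance density; monotone non-increasing in ``t`` and
    equal to ``exp(-t/2N)`` in the neutral limit.
    """
    taus = np.atleast_1d(np.asarray(t, dtype=float))
    vd = equilibrium_variance_density(cfg, _check_mass=False)
    if method == "closed_form":
        if cfg.neutral:
            out = np.exp(-taus / (2.0 * cfg.N))
            return out if np.ndim(t) else float(out[0])
        R = np.array([[closed_form_retention(a, tt, cfg.N, cfg.w, cfg.V_P).product
                       for a in vd.effects] for tt in taus])
    elif method == "diffusion":
        if cfg.neutral:
            R = np.exp(-taus / (2.0 * cfg.N))[:, None] * np.ones(len(vd.effects))
        else:
            R = np.array([diffusion_retention(a, taus, cfg.N, cfg.w, cfg.V_P,
                                              cfg.n_freq)
                          for a in vd.effects]).T
    else:
        raise ValueError(f"unknown method {method!r}")
    num = np.trapezoid(R * vd.density, vd.effects, axis=1)
    out = num / vd.total
    return out if np.ndim(t) else float(out[0])


# ----------------------------------------------------------------------
# ascertainment-aware shared-variance predictions
# ----------------------------------------------------------------------

def _locus_density_2d(cfg: TheoryConfig, n_freq: int | None = None):
    """Joint stationary density of (effect, frequency) for segregating loci.

    Returns (a grid, interior x grid, weight matrix W[i, j] = expected
    number of segregating loci per cell).
    """
    n_freq = n_freq or cfg.n_freq
    scale = cfg.effect_scale
    a = cfg.effect_dist.quantile_grid(cfg.n_effect, scale=scale)
    mu2 = 2.0 * cfg.effect_dist.pdf(a, scale=scale)
    da = np.gradient(a)
    x = _freq_grid(n_freq)
    xi = x[1:-1]
    wq = _interior_weights(x)
    if cfg.neutral:
        S = np.zeros_like(a)
    else:
        S = 2.0 * cfg.N * a**2 / (cfg.w**2 + cfg.V_P)
    W = np.empty((len(a), len(xi)))
    for i, s in enumerate(S):
        W[i] = cfg.N * cfg.U * mu2[i] * da[i] * sojourn_density(s, cfg.N, xi) * wq
    return a, xi, W


def top_variance_share(cfg: TheoryConfig, q: float = 0.05) -> float:
    """Equilibrium share of genic variance explained by the top ``q`` fraction
    of segregating loci ranked by per-locus variance ``2 p q a^2``."""
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    a, xi, W = _locus_density_2d(cfg)
    V = 2.0 * xi[None, :] * (1.0 - xi[None, :]) * a[:, None] ** 2
    w_flat = W.ravel()
    v_flat = V.ravel()
    order = np.argsort(v_flat)[::-1]
    cum = np.cumsum(w_flat[order])
    n_top = cum[-1] * q
    k = int(np.searchsorted(cum, n_top))
    top = order[:k + 1]
    return float(np.sum(w_flat[top] * v_flat[top]) / np.sum(w_flat * v_flat))


def _variance_threshold(cfg: TheoryConfig, q: float) -> float:
    """Per-locus variance cutoff delimiting the top ``q`` fraction of loci."""
    a, xi, W = _locus_density_2d(cfg)
    V = 2.0 * xi[None, :] * (1.0 - xi[None, :]) * a[:, None] ** 2
    w_flat, v_flat = W.ravel(), V.ravel()
    order = np.argsort(v_flat)[::-1]
    cum = np.cumsum(w_flat[order])
    k = int(np.searchsorted(cum, cum[-1] * q))
    return float(v_flat[order[min(k, len(order) - 1)]])


def shared_variance_ratio(cfg: TheoryConfig, t: float | np.ndarray,
                          scheme=None) -> np.ndarray | float:
    """Predicted prediction-accuracy in population B relative to population A.

    Populations A and B split ``t`` generations ago from a common
    equilibrium ancestor and evolve independently; a polygenic score is
    built from loci ascertained in A.  An ancestral locus contributes to
    the score's variance in B only if it still segregates in B *and* was
    ascertained in A, the two lineages evolving independently from the
    ancestral frequency.  Both populations remain at equilibrium, so the
    denominator of each accuracy is the equilibrium genic variance.

    ``scheme`` is an :class:`~polyport.ascertainment.AscertainmentScheme`
    (``None`` means ascertain everything segregating in A).  For subset
    schemes the A-side variance share is taken at equilibrium.
    """
    from .ascertainment import AscertainmentScheme  # local: avoid cycle

    if scheme is None:
        scheme = AscertainmentScheme(kind="all")
    taus = np.atleast_1d(np.asarray(t, dtype=float)) / (2.0 * cfg.N)
    a_grid, xi, W = _locus_density_2d(cfg)
    h = 2.0 * xi * (1.0 - xi)
    V_eq = float(np.sum(W * (h[None, :] * a_grid[:, None] ** 2)))

    if scheme.kind == "top_variance_fraction":
        vstar = _variance_threshold(cfg, scheme.q)
        ratio_A = top_variance_share(cfg, scheme.q)
    elif scheme.kind == "maf_threshold":
        keep = (np.minimum(xi, 1.0 - xi) > scheme.m).astype(float)
        ratio_A = float(np.sum(W * (keep * h)[None, :] * a_grid[:, None] ** 2) / V_eq)
    else:
        ratio_A = 1.0

    if cfg.neutral:
        S_of = np.zeros_like(a_grid)
    else:
        S_of = 2.0 * cfg.N * a_grid**2 / (cfg.w**2 + cfg.V_P)
    x = _freq_grid(cfg.n_freq)

    shared = np.zeros((len(taus),))
    for i, (aa, s) in enumerate(zip(a_grid, S_of)):
        if scheme.kind == "top_variance_fraction":
            ind = (h * aa * aa > vstar).astype(float)
        elif scheme.kind == "maf_threshold":
            ind = (np.minimum(xi, 1.0 - xi) > scheme.m).astype(float)
        else:
            ind = np.ones_like(xi)
        u_h = _propagate_backward(s, x, h, taus)        # E[H_B | x0]
        u_ind = _propagate_backward(s, x, ind, taus)    # P(ascertained in A | x0)
        shared += (u_h * u_ind * W[i][None, :]).sum(axis=1) * aa * aa
    out = shared / V_eq / ratio_A
    return out if np.ndim(t) else float(out[0])


# ----------------------------------------------------------------------
# equilibrium sampler used by the simulator's warm start
# ----------------------------------------------------------------------

def _sojourn_total(S: float, N: int, n_freq: int = 400) -> float:
    """Expected segregating lifetime (generations) of one new mutation."""
    x = _freq_grid(n_freq)
    xi = x[1:-1]
    wq = _interior_weights(x)
    return float(np.sum(wq * sojourn_density(S, N, xi)))


def sample_equilibrium_loci(N: int, U: float, w: float | None,
                            effect_dist: EffectDistribution, scale: float,
                            rng: np.random.Generator,
                            n_fixed: int | None = None,
                            n_freq: int = 300):
    """Draw (effects, frequencies) from the stationary locus distribution.

    The number of segregating loci is Poisson with mean
    ``N U * E_mu[T_sojourn(S(a))]``; each locus's effect is drawn from the
    mutational density tilted by its expected lifetime, and its frequency
    from the sojourn density for its own ``S`` (bucketed on an S grid).
    With ``n_fixed`` given, exactly that many loci are drawn instead
    (used for neutral marker panels).  Effects are returned with random
    signs; pass ``w=None`` for neutral loci.
    """
    neutral = w is None or math.isinf(w)
    x = _freq_grid(n_freq)
    xi = x[1:-1]
    wq = _interior_weights(x)

    if neutral:
        S_grid = np.array([0.0])
    else:
        S_grid = np.concatenate([[0.0], np.geomspace(0.05, _S_CAP, 64)])
    T_grid = np.array([_sojourn_total(s, N, n_freq) for s in S_grid])
    # per-S inverse CDF table of the sojourn density
    cdfs = []
    for s in S_grid:
        dens = sojourn_density(s, N, xi) * wq
        c = np.cumsum(dens)
        cdfs.append(c / c[-1])
    cdfs = np.array(cdfs)

    def s_index(S_vals):
        return np.argmin(np.abs(np.log1p(S_grid)[None, :]
                                - np.log1p(S_vals)[:, None]), axis=1)

    if n_fixed is not None:
        count = n_fixed
        if neutral:
            effects = np.zeros(count)
        else:
            effects = effect_dist.sample(count, rng, scale=scale)
    else:
        # expected segregating count: accept-reject against the neutral lifetime
        probe = np.abs(effect_dist.sample(4000, rng, scale=scale))
        if neutral:
            T_probe = np.full(len(probe), T_grid[0])
        else:
            Sp = 2.0 * N * probe**2 / w**2
            T_probe = np.interp(np.log1p(Sp), np.log1p(S_grid), T_grid)
        lam = N * U * float(np.mean(T_probe))
        count = int(rng.poisson(lam))
        effects = np.empty(count)
        got = 0
        Tmax = T_grid[0]  # neutral lifetime bounds all others
        while got < count:
            cand = effect_dist.sample(2 * (count - got) + 16, rng, scale=scale)
            if neutral:
                Tc = np.full(len(cand), T_grid[0])
            else:
                Sc = 2.0 * N * cand**2 / w**2
                Tc = np.interp(np.log1p(Sc), np.log1p(S_grid), T_grid)
            keep = cand[rng.random(len(cand)) < Tc / Tmax]
            take = min(len(keep), count - got)
            effects[got:got + take] = keep[:take]
            got += take

    if neutral:
        idx = np.zeros(len(effects), dtype=int)
    else:
        S_eff = 2.0 * N * effects**2 / w**2
        idx = s_index(S_eff)
    u = rng.random(len(effects))
    freqs = np.empty(len(effects))
    for k in np.unique(idx):
        sel = idx == k
        freqs[sel] = np.interp(u[sel], cdfs[k], xi)
    return effects, freqs
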