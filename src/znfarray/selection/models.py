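"""Site-model fitting (M0, M1a, M2a, M3, M7, M8) and nested LRTs.

Each model is a mixture of omega classes shared across sites.  Proportions
are optimized on the simplex through a stick-breaking transform, rate
parameters through log transforms, all inside box bounds handled by
L-BFGS-B.  The beta distributions of M7/M8 are discretized into ``ncat``
equal-probability categories (quantile midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .alignment import CodonAlignment
from .codon import GOLDMAN_WHELAN
from .likelihood import MixtureLikelihood
from .trees import PhyloTree, neighbor_joining_tree

MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8")

#: Recognized nested pairs and their degrees of freedom.
NESTED_PAIRS: dict[tuple[str, str], int] = {
    ("M0", "M3"): 4,
    ("M1a", "M2a"): 2,
    ("M7", "M8"): 2,
}

_LN = np.log
_K_BOUNDS = (_LN(0.1), _LN(50.0))
_W_BOUNDS = (_LN(1e-4), _LN(50.0))
_W0_BOUNDS = (_LN(1e-4), _LN(0.9999))  # purifying class, omega < 1
_WPOS_BOUNDS = (0.0, _LN(50.0))  # selection class, omega >= 1
_Z_BOUNDS = (-12.0, 12.0)
_BETA_BOUNDS = (_LN(0.005), _LN(99.0))
_BL_BOUNDS = (_LN(1e-6), _LN(20.0))


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _stick_break(zs: Sequence[float]) -> np.ndarray:
    """Map len(zs) unconstrained values to a len(zs)+1 simplex point."""
    props = []
    rest = 1.0
    for z in zs:
        p = rest * _sigmoid(z)
        props.append(p)
        rest -= p
    props.append(rest)
    return np.array(props)


def discretize_beta(p: float, q: float, ncat: int) -> np.ndarray:
    """Quantile midpoints of Beta(p, q), one per equal-probability category."""
    qs = (np.arange(ncat) + 0.5) / ncat
    return np.clip(beta_dist.ppf(qs, p, q), 1e-8, 1 - 1e-8)


@dataclass
class SiteModelFit:
    """Maximum-likelihood fit of one site model."""

    model: str
    lnL: float
    kappa: float
    proportions: tuple[float, ...]
    omegas: tuple[float, ...]
    beta_params: tuple[float, float] | None
    codon_freq_model: str
    style: str
    branch_lengths: tuple[float, ...]
    tree_newick: str
    branch_lengths_estimated: bool
    ncat: int
    n_restarts: int
    converged: bool

    @property
    def has_selection_class(self) -> bool:
        return self.model in ("M2a", "M8")

    @property
    def omega_positive(self) -> float:
        """The omega of the positive-selection class (M2a/M8)."""
        if not self.has_selection_class:
            raise ValueError(f"model {self.model} has no positive-selection class")
        return self.omegas[-1]

    @property
    def p_positive(self) -> float:
        if not self.has_selection_class:
            raise ValueError(f"model {self.model} has no positive-selection class")
        return self.proportions[-1]


@dataclass(frozen=True)
class LrtResult:
    null_model: str
    alt_model: str
    two_delta_l: float
    df: int
    p_value: float


def _model_layout(model: str, ncat: int):
    """Initial parameter vector (transformed space) and bounds per model."""
    k0 = _LN(2.0)
    if model == "M0":
        return [k0, _LN(0.4)], [_K_BOUNDS, _W_BOUNDS]
    if model == "M1a":
        return [k0, _logit(0.7), _LN(0.1)], [_K_BOUNDS, _Z_BOUNDS, _W0_BOUNDS]
    if model == "M2a":
        return (
            [k0, _logit(0.7), _logit(0.7), _LN(0.1), _LN(3.0)],
            [_K_BOUNDS, _Z_BOUNDS, _Z_BOUNDS, _W0_BOUNDS, _WPOS_BOUNDS],
        )
    if model == "M3":
        return (
            [k0, _logit(1 / 3), _logit(0.5), _LN(0.05), _LN(0.5), _LN(3.0)],
            [_K_BOUNDS, _Z_BOUNDS, _Z_BOUNDS, _W_BOUNDS, _W_BOUNDS, _W_BOUNDS],
        )
    if model == "M7":
        return [k0, _LN(1.0), _LN(2.0)], [_K_BOUNDS, _BETA_BOUNDS, _BETA_BOUNDS]
    if model == "M8":
        return (
            [k0, _logit(0.9), _LN(1.0), _LN(2.0), _LN(3.0)],
            [_K_BOUNDS, _Z_BOUNDS, _BETA_BOUNDS, _BETA_BOUNDS, _WPOS_BOUNDS],
        )
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _unpack(model: str, theta: np.ndarray, ncat: int):
    """Transformed parameters -> (kappa, proportions, omegas, beta_params)."""
    kappa = float(np.exp(theta[0]))
    if model == "M0":
        return kappa, np.array([1.0]), np.array([np.exp(theta[1])]), None
    if model == "M1a":
        p0 = _sigmoid(theta[1])
        return kappa, np.array([p0, 1 - p0]), np.array([np.exp(theta[2]), 1.0]), None
    if model == "M2a":
        props = _stick_break(theta[1:3])
        omegas = np.array([np.exp(theta[3]), 1.0, np.exp(theta[4])])
        return kappa, props, omegas, None
    if model == "M3":
        props = _stick_break(theta[1:3])
        return kappa, props, np.exp(theta[3:6]), None
    if model == "M7":
        p, q = np.exp(theta[1]), np.exp(theta[2])
        omegas = discretize_beta(p, q, ncat)
        return kappa, np.full(ncat, 1.0 / ncat), omegas, (float(p), float(q))
    if model == "M8":
        p0 = _sigmoid(theta[1])
        p, q = np.exp(theta[2]), np.exp(theta[3])
        omegas = np.append(discretize_beta(p, q, ncat), np.exp(theta[4]))
        props = np.append(np.full(ncat, p0 / ncat), 1 - p0)
        return kappa, props, omegas, (float(p), float(q))
    raise ValueError(f"unknown model {model!r}")


def fit_site_model(
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    model: str = "M0",
    codon_freq_model: str = "F3x4",
    style: str = GOLDMAN_WHELAN,
    n_restarts: int = 3,
    optimize_branch_lengths: bool = True,
    ncat: int = 10,
    seed: int = 0,
    maxiter: int = 500,
) -> SiteModelFit:
    """Fit one site model by bounded quasi-Newton with random restarts.

    If ``tree`` is ``None`` a neighbor-joining fallback tree is built from
    the alignment.  With ``optimize_branch_lengths`` the branch lengths are
    estimated jointly with the model parameters (in log space); otherwise
    they are fixed at the input tree's values.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if aln.n_taxa < 3:
        raise ValueError("site-model fits require at least 3 taxa")
    if tree is None:
        tree = neighbor_joining_tree(aln)
    engine = MixtureLikelihood(aln, tree, codon_freq_model, style)
    theta0, bounds = _model_layout(model, ncat)
    n_model = len(theta0)
    fixed_bl = engine.index.branch_lengths.copy()
    if optimize_branch_lengths:
        bl0 = np.log(np.maximum(fixed_bl, 1e-3))
        theta0 = list(theta0) + list(bl0)
        bounds = list(bounds) + [_BL_BOUNDS] * len(bl0)

    def negll(theta: np.ndarray) -> float:
        kappa, props, omegas, _ = _unpack(model, theta, ncat)
        bl = np.exp(theta[n_model:]) if optimize_branch_lengths else fixed_bl
        val = engine.evaluate(kappa, omegas, props, bl).lnL
        if not np.isfinite(val):
            return 1e12
        return -val

    rng = np.random.default_rng(seed)
    theta0 = np.array(theta0)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    any_success = False
    for r in range(max(1, n_restarts)):
        x0 = theta0 if r == 0 else np.clip(theta0 + rng.normal(0, 0.75, theta0.size), lo, hi)
        res = minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    kappa, props, omegas, beta_params = _unpack(model, best.x, ncat)
    bl = np.exp(best.x[n_model:]) if optimize_branch_lengths else fixed_bl
    fitted_tree = tree.copy()
    if optimize_branch_lengths:
        # postorder order matches engine.index ordering
        fitted_tree.set_branch_lengths(bl)
    return SiteModelFit(
        model=model,
        lnL=float(-best.fun),
        kappa=kappa,
        proportions=tuple(float(p) for p in props),
        omegas=tuple(float(w) for w in omegas),
        beta_params=beta_params,
        codon_freq_model=engine.freqs.model,
        style=style,
        branch_lengths=tuple(float(t) for t in bl),
        tree_newick=fitted_tree.to_newick(),
        branch_lengths_estimated=optimize_branch_lengths,
        ncat=ncat,
        n_restarts=max(1, n_restarts),
        converged=any_success,
    )


def likelihood_ratio_test(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LrtResult:
    """Chi-square LRT of a recognized nested model pair.

    The statistic 2(lnL_alt - lnL_null) is clipped at zero (boundary
    optimizer noise); the p-value is the chi-square upper tail at the
    pair's degrees of freedom.
    """
    pair = (null_fit.model, alt_fit.model)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"unrecognized nested pair {pair}; expected one of {sorted(NESTED_PAIRS)}")
    df = NESTED_PAIRS[pair]
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    return LrtResult(
        null_model=null_fit.model,
        alt_model=alt_fit.model,
        two_delta_l=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
    )


def chi2_upper_tail(statistic: float, df: int) -> float:
    """Chi-square survival function used for the printed LRT statistics."""
    return float(chi2.sf(statistic, df))
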