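"""Empirical-Bayes classification of sites into omega classes.

NEB (naive empirical Bayes, the default) plugs the maximum-likelihood
mixture parameters into Bayes' rule per site.  BEB integrates over a grid
of mixture parameters with a uniform prior (implemented for M2a); it is
provided behind a flag because the plug-in method is the package default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .likelihood import MixtureLikelihood
from .models import SiteModelFit
from .trees import PhyloTree

NEB = "NEB"
BEB = "BEB"


@dataclass
class SitePosterior:
    """Per-site posterior membership in the omega classes of a fitted model.

    ``p_selected`` is the posterior probability of the positive-selection
    class; ``post_mean_omega``/``post_sd_omega`` are the posterior mean and
    standard deviation of omega per site.
    """

    method: str
    model: str
    omegas: tuple[float, ...]
    proportions: tuple[float, ...]
    class_posteriors: np.ndarray  # (n_classes, n_sites)
    p_selected: np.ndarray  # (n_sites,)
    post_mean_omega: np.ndarray
    post_sd_omega: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.p_selected.shape[0]

    def top_sites(self) -> np.ndarray:
        """Site indices ordered by decreasing selection posterior."""
        return np.argsort(-self.p_selected, kind="stable")


def _posterior_from_logf(log_f: np.ndarray, props: np.ndarray) -> np.ndarray:
    lw = np.log(np.maximum(props, 1e-300))[:, None]
    log_post = log_f + lw
    return np.exp(log_post - logsumexp(log_post, axis=0, keepdims=True))


def _summaries(post: np.ndarray, omegas: np.ndarray):
    mean = (post * omegas[:, None]).sum(axis=0)
    second = (post * (omegas**2)[:, None]).sum(axis=0)
    sd = np.sqrt(np.maximum(second - mean**2, 0.0))
    return mean, sd


def empirical_bayes_site_classes(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    method: str = NEB,
    beb_grid: int = 10,
    freqs=None,
) -> SitePosterior:
    """Posterior site classification under a fitted M2a or M8 model.

    The tree defaults to the fitted tree (with its estimated branch
    lengths).  Raises for models without a positive-selection class.
    """
    if not fit.has_selection_class:
        raise ValueError(f"model {fit.model} has no positive-selection class")
    if method not in (NEB, BEB):
        raise ValueError(f"method must be {NEB!r} or {BEB!r}")
    if tree is None:
        tree = PhyloTree.from_newick(fit.tree_newick)
    engine = MixtureLikelihood(aln, tree, fit.codon_freq_model, fit.style, freqs=freqs)
    bl = np.array(fit.branch_lengths)

    if method == NEB:
        ev = engine.evaluate(fit.kappa, fit.omegas, fit.proportions, bl)
        post = engine.expand(_posterior_from_logf(ev.log_f, np.array(fit.proportions)))
        omegas = np.array(fit.omegas)
        mean, sd = _summaries(post, omegas)
        return SitePosterior(
            method=NEB,
            model=fit.model,
            omegas=fit.omegas,
            proportions=fit.proportions,
            class_posteriors=post,
            p_selected=post[-1],
            post_mean_omega=mean,
            post_sd_omega=sd,
        )

    if fit.model != "M2a":
        raise NotImplementedError("BEB grid integration is implemented for M2a only; use NEB for M8")
    return _beb_m2a(fit, engine, bl, beb_grid)


def _beb_m2a(fit: SiteModelFit, engine: MixtureLikelihood, bl: np.ndarray, d: int) -> SitePosterior:
    """Grid-integration BEB for M2a with a uniform prior over the grid.

    Grid: omega0 on (0,1), omega2 on (1,11), (p0, p1) on the simplex
    triangle, all with ``d`` midpoint values per dimension.
    """
    w0_grid = (np.arange(d) + 0.5) / d
    w2_grid = 1.0 + 10.0 * (np.arange(d) + 0.5) / d
    # per-site log likelihood vectors for every omega the grid can use
    logf_w0 = [engine.class_log_f(fit.kappa, w, bl, scale=_mix_scale(fit, engine)) for w in w0_grid]
    logf_w1 = engine.class_log_f(fit.kappa, 1.0, bl, scale=_mix_scale(fit, engine))
    logf_w2 = [engine.class_log_f(fit.kappa, w, bl, scale=_mix_scale(fit, engine)) for w in w2_grid]

    pgrid = [
        (a, b, 1.0 - a - b)
        for a, b in itertools.product((np.arange(d) + 0.5) / d, repeat=2)
        if a + b < 1.0
    ]
    weights = engine.weights
    npat = engine.n_patterns
    post_acc = np.zeros((3, npat))
    log_marg = []
    combos = []
    for (p0, p1, p2), i0, i2 in itertools.product(pgrid, range(d), range(d)):
        logf = np.vstack([logf_w0[i0], logf_w1, logf_w2[i2]])
        lw = np.log(np.array([p0, p1, p2]))[:, None]
        site_log = logsumexp(logf + lw, axis=0)
        log_marg.append(float(site_log @ weights))
        combos.append((logf, np.array([p0, p1, p2])))
    log_marg = np.array(log_marg)
    grid_post = np.exp(log_marg - logsumexp(log_marg))
    for gp, (logf, props) in zip(grid_post, combos):
        if gp < 1e-12:
            continue
        post_acc += gp * _posterior_from_logf(logf, props)
    post = engine.expand(post_acc)
    # posterior omega summaries use the grid-averaged class omegas
    omegas = np.array([float(w0_grid.mean()), 1.0, float(w2_grid.mean())])
    mean, sd = _summaries(post, omegas)
    return SitePosterior(
        method=BEB,
        model=fit.model,
        omegas=tuple(omegas),
        proportions=fit.proportions,
        class_posteriors=post,
        p_selected=post[-1],
        post_mean_omega=mean,
        post_sd_omega=sd,
    )


def _mix_scale(fit: SiteModelFit, engine: MixtureLikelihood) -> float:
    """Rate normalizer of the fitted mixture (keeps branch lengths comparable)."""
    from .codon import rate_matrix

    comps = [rate_matrix(fit.kappa, w, engine.freqs, engine.style) for w in fit.omegas]
    return float(sum(p * r for p, (_, _, r) in zip(fit.proportions, comps)))
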