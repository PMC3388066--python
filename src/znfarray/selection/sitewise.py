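"""Sitewise likelihood-ratio test of per-site omega against neutrality.

Global nuisance parameters (kappa and branch lengths) are estimated once
under the single-ratio model; each site's omega is then maximized on its
own and compared against omega = 1 by a likelihood-ratio statistic.  The
test is one-tailed for positive selection: p = 0.5 * chi2_1 upper tail when
the site's omega exceeds 1 (the half accounts for the boundary mixture),
p = 1 otherwise.  Multiple testing is corrected with Holm–Bonferroni by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .codon import GOLDMAN_WHELAN, MUSE_GAUT
from .likelihood import MixtureLikelihood
from .models import fit_site_model
from .trees import PhyloTree

_W_LO, _W_HI = 1e-4, 50.0


@dataclass
class SitewiseResult:
    omegas: np.ndarray  # per-site omega-hat (NaN for invariant sites)
    statistics: np.ndarray  # per-site LRT statistic vs omega = 1
    p_values: np.ndarray  # one-tailed, for omega > 1
    significant_05: np.ndarray  # after multiple-testing correction
    significant_01: np.ndarray
    invariant: np.ndarray  # sites with a single observed codon
    kappa: float
    freq_incorporation: str
    codon_freq_model: str
    correction: str

    @property
    def n_sites(self) -> int:
        return self.omegas.shape[0]


def sitewise_selection_test(
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    codon_freq_model: str = "F3x4",
    freq_incorporation: str = MUSE_GAUT,
    correction: str = "holm",
    n_restarts: int = 2,
    grid_size: int = 121,
    seed: int = 0,
) -> SitewiseResult:
    """Per-site omega estimation and one-tailed neutrality test.

    ``freq_incorporation`` selects how codon frequencies enter the rate
    matrix (``musegaut`` or ``goldmanwhelan``).  Invariant sites have an
    undefined omega and are reported as non-significant with a flag.
    """
    if freq_incorporation not in (MUSE_GAUT, GOLDMAN_WHELAN):
        raise ValueError(f"unknown freq_incorporation {freq_incorporation!r}")
    ref = fit_site_model(
        aln,
        tree,
        model="M0",
        codon_freq_model=codon_freq_model,
        style=freq_incorporation,
        n_restarts=n_restarts,
        optimize_branch_lengths=True,
        seed=seed,
    )
    fitted_tree = PhyloTree.from_newick(ref.tree_newick)
    engine = MixtureLikelihood(aln, fitted_tree, codon_freq_model, freq_incorporation)
    bl = np.array(ref.branch_lengths)
    kappa = ref.kappa

    # branch lengths are interpreted on the reference model's rate scale
    from .codon import rate_matrix

    _, _, ref_rate = rate_matrix(kappa, ref.omegas[0], engine.freqs, freq_incorporation)

    def logf_for(omega: float, cols: np.ndarray | None = None) -> np.ndarray:
        return engine.class_log_f(kappa, omega, bl, scale=ref_rate, pattern_cols=cols)

    # coarse log-spaced grid (1.0 included exactly) shared across sites
    grid = np.unique(np.concatenate([np.geomspace(_W_LO, _W_HI, grid_size), [1.0]]))
    logf_grid = np.vstack([logf_for(w) for w in grid])  # (n_grid, n_patterns)
    logf_neutral = logf_grid[int(np.searchsorted(grid, 1.0))]

    npat = engine.n_patterns
    pat_omega = np.empty(npat)
    pat_stat = np.empty(npat)
    pat_invariant = np.zeros(npat, dtype=bool)
    for h in range(npat):
        col = engine.patterns[:, h]
        if np.all(col == col[0]):
            pat_invariant[h] = True
            pat_omega[h] = np.nan
            pat_stat[h] = 0.0
            continue
        k = int(np.argmax(logf_grid[:, h]))
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        colsel = np.array([h])

        def neg(logw: float) -> float:
            return -float(logf_for(float(np.exp(logw)), colsel)[0])

        res = minimize_scalar(
            neg, bounds=(np.log(lo), np.log(hi)), method="bounded", options={"xatol": 1e-3}
        )
        best_logf = max(-res.fun, float(logf_grid[k, h]))
        w_hat = float(np.exp(res.x)) if -res.fun >= logf_grid[k, h] else float(grid[k])
        pat_omega[h] = w_hat
        pat_stat[h] = max(0.0, 2.0 * (best_logf - float(logf_neutral[h])))

    omegas = engine.expand(pat_omega)
    stats = engine.expand(pat_stat)
    invariant = engine.expand(pat_invariant.astype(float)) > 0.5
    pvals = np.where(
        invariant | ~(omegas > 1.0),
        1.0,
        0.5 * chi2.sf(stats, 1),
    )
    sig05 = multipletests(pvals, alpha=0.05, method=correction)[0]
    sig01 = multipletests(pvals, alpha=0.01, method=correction)[0]
    return SitewiseResult(
        omegas=omegas,
        statistics=stats,
        p_values=pvals,
        significant_05=sig05,
        significant_01=sig01,
        invariant=invariant,
        kappa=kappa,
        freq_incorporation=freq_incorporation,
        codon_freq_model=codon_freq_model,
        correction=correction,
    )
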