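"""Gene essentiality from transposon insertion data.

The insertion index of gene i is its per-bp insertion rate normalized by the
local rate of a 100-gene window around it:

    II_i = (n_i / k_i) / (n_r / k_r)

II is bimodal: essential genes tolerate almost no insertions.  A two-component
gamma mixture is fitted to the II distribution by EM, and a fivefold density
ratio between the components defines the lower (essential) and upper
(non-essential) thresholds; genes in between are "probably essential"
(ambiguous).  Gene calls propagate to reactions through the GPR: any essential
gene makes the reaction essential, else any probably-essential gene makes it
probably essential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synth import InsertionTable

log = logging.getLogger("necalloc")

ESSENTIAL = "essential"
PROBABLY = "probably_essential"
NON_ESSENTIAL = "non_essential"


def central_orf_filter(
    table: InsertionTable, central_fraction: float = 0.8
) -> InsertionTable:
    """Keep only insertions within the central part of each ORF (true
    knockouts); with the default 0.8 that is positions in [0.1, 0.9]."""
    lo = (1.0 - central_fraction) / 2.0
    hi = 1.0 - lo
    positions = {}
    for gene, pos in table.positions.items():
        pos = np.asarray(pos, dtype=float)
        if pos.size and (pos.min() < 0 or pos.max() > 1):
            raise ValueError(f"gene {gene}: insertion positions outside [0, 1]")
        positions[gene] = pos[(pos >= lo) & (pos <= hi)]
    return InsertionTable(genes=table.genes.copy(), positions=positions)


def insertion_index(table: InsertionTable, window_genes: int = 100,
                    circular: bool = False) -> pd.Series:
    """II per gene using a window of ``window_genes`` genes centered on the
    target (target included), truncated at replicon ends unless ``circular``.

    Genes whose window has zero insertions get NaN (undefined, flagged by the
    caller)."""
    genes = table.genes.sort_values("order").reset_index(drop=True)
    n = np.array([len(table.positions[g]) for g in genes["gene"]], dtype=float)
    k = genes["length_bp"].to_numpy(dtype=float)
    m = len(genes)
    half = window_genes // 2
    ii = np.full(m, np.nan)
    for i in range(m):
        if circular:
            idx = (np.arange(i - half, i - half + window_genes)) % m
        else:
            lo = max(0, i - half)
            hi = min(m, lo + window_genes)
            lo = max(0, hi - window_genes)
            idx = np.arange(lo, hi)
        nr, kr = n[idx].sum(), k[idx].sum()
        if nr > 0:
            ii[i] = (n[i] / k[i]) / (nr / kr)
    return pd.Series(ii, index=genes["gene"].to_numpy(), name="II")


# ---------------------------------------------------------------------------
# two-gamma mixture


@dataclass
class GammaMixture:
    shape_low: float
    scale_low: float
    shape_high: float
    scale_high: float
    weight_low: float  # mixing weight of the low (essential) component
    converged: bool = True
    log_likelihood: float = float("nan")
    degenerate: bool = False

    def density_low(self, x):
        return stats.gamma.pdf(x, self.shape_low, scale=self.scale_low)

    def density_high(self, x):
        return stats.gamma.pdf(x, self.shape_high, scale=self.scale_high)

    @property
    def mean_low(self) -> float:
        return self.shape_low * self.scale_low

    @property
    def mean_high(self) -> float:
        return self.shape_high * self.scale_high


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via the digamma equation; moment fallback."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    mean_log = float((w * np.log(x)).sum() / wsum)
    s = np.log(mean) - mean_log
    if s <= 0:  # numerically degenerate (near-constant data)
        var = float((w * (x - mean) ** 2).sum() / wsum)
        shape = mean * mean / var if var > 0 else 1e6
        return shape, mean / shape

    def f(a):
        return np.log(a) - special.digamma(a) - s

    # standard initial guess, then bracket and solve
    a0 = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    lo, hi = a0 / 10, a0 * 10
    while f(lo) < 0 and lo > 1e-8:
        lo /= 10
    while f(hi) > 0 and hi < 1e8:
        hi *= 10
    try:
        shape = optimize.brentq(f, lo, hi)
    except ValueError:
        shape = a0
    return shape, mean / shape


def _antimode_split(x: np.ndarray) -> float:
    """Initial low/high split at the empirical antimode.

    Located by two-means clustering of log(II), which separates the two modes
    of a bimodal distribution regardless of their relative heights; the split
    falls in the density valley between the cluster boundaries."""
    lx = np.sort(np.log(x))
    c1, c2 = lx[0], lx[-1]
    assign = np.zeros(lx.size, dtype=bool)
    for _ in range(100):
        assign = np.abs(lx - c1) <= np.abs(lx - c2)
        if assign.all() or not assign.any():
            return float(np.median(x)) / 2.0
        n1, n2 = lx[assign].mean(), lx[~assign].mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return float(np.exp(0.5 * (lx[assign].max() + lx[~assign].min())))


def fit_gamma_mixture(
    ii: pd.Series | np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GammaMixture:
    """Fit a two-gamma mixture to insertion indices by EM.

    Zeros (gamma densities have no support at 0) are spread evenly over the
    interval up to half the smallest positive value, preserving "essentially
    never hit" as a low-II population with nonzero width instead of a point
    mass no gamma can represent.  Moment-based initialization from a split at
    the empirical antimode; weighted-MLE M-step.  A collapse of either mixing
    weight flags a degenerate fit.
    """
    x = np.asarray(pd.Series(ii).dropna(), dtype=float)
    if np.any(x < 0):
        raise ValueError("insertion indices must be >= 0")
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("all insertion indices are zero")
    zeros = np.flatnonzero(x == 0)
    if zeros.size:
        half_min = positive.min() / 2.0
        x = x.copy()
        x[zeros] = half_min * np.arange(1, zeros.size + 1) / zeros.size

    split = _antimode_split(x)
    low, high = x[x <= split], x[x > split]
    if low.size < 2 or high.size < 2:
        mix = _single_component(x)
        log.warning("gamma mixture: no antimode separation; degenerate fit")
        return mix
    w_low = np.where(x <= split, 1.0, 0.0)
    pi = w_low.mean()
    sh_l, sc_l = _weighted_gamma_mle(x, w_low)
    sh_h, sc_h = _weighted_gamma_mle(x, 1 - w_low)

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        d_l = pi * stats.gamma.pdf(x, sh_l, scale=sc_l)
        d_h = (1 - pi) * stats.gamma.pdf(x, sh_h, scale=sc_h)
        total = d_l + d_h
        total = np.where(total > 0, total, 1e-300)
        r = d_l / total
        ll = float(np.log(total).sum())
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
        pi = float(r.mean())
        if pi < 1e-6 or pi > 1 - 1e-6:
            break  # weight collapse -> degenerate
        sh_l, sc_l = _weighted_gamma_mle(x, r)
        sh_h, sc_h = _weighted_gamma_mle(x, 1 - r)

    # orient components: low-mean first
    if sh_l * sc_l > sh_h * sc_h:
        sh_l, sc_l, sh_h, sc_h, pi = sh_h, sc_h, sh_l, sc_l, 1 - pi
    # a collapsed weight or coinciding components mean one population:
    # the mixture is over-parameterized and the fit is flagged degenerate
    coincide = abs(sh_l * sc_l - sh_h * sc_h) < 0.5 * sh_h * sc_h
    degenerate = pi < 0.01 or pi > 0.99 or (not converged and coincide)
    if not converged and not degenerate:
        raise RuntimeError(
            f"gamma-mixture EM did not converge after {max_iter} iterations "
            f"(last: shapes {sh_l:.3g}/{sh_h:.3g}, weight {pi:.3g})"
        )
    return GammaMixture(sh_l, sc_l, sh_h, sc_h, pi, converged=converged,
                        log_likelihood=ll, degenerate=degenerate)


def _single_component(x: np.ndarray) -> GammaMixture:
    sh, sc = _weighted_gamma_mle(x, np.ones_like(x))
    return GammaMixture(sh, sc, sh, sc, 0.0, converged=True, degenerate=True,
                        log_likelihood=float(stats.gamma.logpdf(x, sh, scale=sc).sum()))


# ---------------------------------------------------------------------------
# classification


def density_ratio_thresholds(
    fit: GammaMixture, fold: float = 5.0, ii_max: float | None = None,
    resolution: float = 1e-4,
) -> tuple[float, float]:
    """Thresholds from a ``fold`` difference of the weighted component
    densities, searched on a dense II grid.

    lower = largest II with p_ess >= fold * p_non; upper = smallest II with
    p_non >= fold * p_ess.  Genes between the two are ambiguous.
    """
    if ii_max is None:
        ii_max = fit.mean_high * 5.0
    grid = np.arange(resolution, ii_max, resolution)
    p_ess = fit.weight_low * fit.density_low(grid)
    p_non = (1 - fit.weight_low) * fit.density_high(grid)
    ess_region = p_ess >= fold * p_non
    non_region = p_non >= fold * p_ess
    lower = float(grid[ess_region].max()) if ess_region.any() else 0.0
    upper = float(grid[non_region].min()) if non_region.any() else float(grid[-1])
    if lower > upper:
        raise ValueError(
            f"essentiality thresholds cross (lower {lower:.4g} > upper "
            f"{upper:.4g}): mixture components not separable"
        )
    return lower, upper


def classify_essentiality(
    ii: pd.Series, fit: GammaMixture, fold: float = 5.0
) -> pd.DataFrame:
    """Per-gene essentiality calls from II values and a fitted mixture.

    II below the lower threshold -> essential; above the upper ->
    non-essential; between (or undefined II) -> probably essential.
    """
    lower, upper = density_ratio_thresholds(fit, fold=fold,
                                            ii_max=float(np.nanmax(ii)) + 1.0)

    def call(v: float) -> str:
        if pd.isna(v):
            return PROBABLY
        if v < lower:
            return ESSENTIAL
        if v > upper:
            return NON_ESSENTIAL
        return PROBABLY

    out = pd.DataFrame({"gene": ii.index, "II": ii.to_numpy()})
    out["class"] = out["II"].map(call)
    out["threshold_lower"] = lower
    out["threshold_upper"] = upper
    return out


def classify_library(
    table: InsertionTable,
    window_genes: int = 100,
    central_fraction: float = 0.8,
    fold: float = 5.0,
) -> pd.DataFrame:
    """Full chain: central-ORF filter -> II -> gamma mixture -> calls."""
    filtered = central_orf_filter(table, central_fraction)
    ii = insertion_index(filtered, window_genes=window_genes)
    fit = fit_gamma_mixture(ii)
    return classify_essentiality(ii, fit, fold=fold)


def propagate_to_reactions(
    calls: pd.DataFrame, network
) -> pd.DataFrame:
    """Reaction essentiality from gene calls through the GPR.

    A reaction is essential if any associated gene is essential, else probably
    essential if any gene is probably essential, else non-essential.
    Reactions without genes are excluded (logged).
    """
    by_gene = dict(zip(calls["gene"], calls["class"]))
    rows = []
    for rxn in network.reactions:
        alts = network.gpr.get(rxn.id)
        if not alts:
            log.info("reaction %s has no genes; excluded from essentiality", rxn.id)
            continue
        genes = sorted({g for eid in alts for g in network.enzymes[eid].composition})
        classes = {by_gene.get(g, NON_ESSENTIAL) for g in genes}
        if ESSENTIAL in classes:
            cls = ESSENTIAL
        elif PROBABLY in classes:
            cls = PROBABLY
        else:
            cls = NON_ESSENTIAL
        rows.append({"reaction": rxn.id, "class": cls, "genes": ";".join(genes)})
    return pd.DataFrame(rows, columns=["reaction", "class", "genes"])
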