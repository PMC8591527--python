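"""Barcoded-mutant fitness scoring (BarSeq).

Per-barcode fitness is the library-size-normalized log2 fold change of read
counts between generation 0 and a later sample:

    f = log2((c_t + psi) / N_t) - log2((c_0 + psi) / N_0)

Gene fitness F aggregates the barcodes of a gene (central-ORF insertions
only) by an inverse-variance weighted mean and is recentered so the median of
designated-neutral genes is zero per sample.  A knockout is called significant
when |F| >= 3 after at least eight generations of competitive growth -- the
bulk of neutral mutants stays within -2 <= F <= 2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synth import BarcodeCounts

log = logging.getLogger("necalloc")

PSEUDOCOUNT = 0.5
F_THRESHOLD = 3.0
MIN_GENERATIONS = 8.0
CENTRAL_WINDOW = (0.1, 0.9)


def barcode_fitness(
    counts_t0: pd.Series, counts_t: pd.Series, pseudocount: float = PSEUDOCOUNT
) -> pd.Series:
    """Per-barcode log2 fold change between two samples of the same library.

    Barcodes with zero counts at both timepoints are excluded (logged)."""
    c0 = counts_t0.astype(float)
    ct = counts_t.reindex(c0.index).astype(float)
    if ct.isna().any():
        raise ValueError("barcode universes of the two samples differ")
    both_zero = (c0 == 0) & (ct == 0)
    if both_zero.any():
        log.info("excluding %d barcodes with zero counts at both timepoints",
                 int(both_zero.sum()))
    c0, ct = c0[~both_zero], ct[~both_zero]
    n0, nt = c0.sum(), ct.sum()
    f = np.log2((ct + pseudocount) / nt) - np.log2((c0 + pseudocount) / n0)
    f.name = "f"
    return f


def _barcode_weights(c0: pd.Series, ct: pd.Series, pseudocount: float) -> pd.Series:
    """Inverse of the Poisson variance of the log ratio (up to a constant)."""
    return 1.0 / (1.0 / (c0 + pseudocount) + 1.0 / (ct + pseudocount))


def gene_fitness(
    counts: BarcodeCounts,
    sample_t0: str,
    sample_t: str,
    pseudocount: float = PSEUDOCOUNT,
    central_window: tuple[float, float] = CENTRAL_WINDOW,
    weighting: str = "inverse_variance",
    neutral_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Gene fitness F between generation 0 and a later sample.

    Barcodes outside the central ORF window are dropped; genes with no usable
    barcode are absent from the output.  ``neutral_genes`` designates the set
    whose median F is recentered to zero (default: all genes).
    """
    if weighting not in ("inverse_variance", "equal"):
        raise ValueError("weighting must be 'inverse_variance' or 'equal'")
    bc = counts.barcodes
    meta = counts.samples.set_index("sample")
    generations = float(meta.loc[sample_t, "generations"])

    central = (bc["position"] >= central_window[0]) & (bc["position"] <= central_window[1])
    usable = bc[central].set_index("barcode")
    if usable.empty:
        raise ValueError("no barcodes within the central ORF window")
    f = barcode_fitness(usable[sample_t0], usable[sample_t], pseudocount)
    genes = usable.loc[f.index, "gene"]
    if weighting == "inverse_variance":
        w = _barcode_weights(usable.loc[f.index, sample_t0],
                             usable.loc[f.index, sample_t], pseudocount)
    else:
        w = pd.Series(1.0, index=f.index)

    df = pd.DataFrame({"gene": genes, "f": f, "w": w})
    agg = df.groupby("gene").apply(
        lambda g: pd.Series({"F": np.average(g["f"], weights=g["w"]),
                             "n_mutants": len(g)}),
        include_groups=False,
    )
    neutral = agg.index if neutral_genes is None else agg.index.intersection(neutral_genes)
    if len(neutral):
        agg["F"] = agg["F"] - agg.loc[neutral, "F"].median()
    out = agg.reset_index()
    out["n_mutants"] = out["n_mutants"].astype(int)
    out["generations"] = generations
    out["sample"] = sample_t
    out["condition"] = meta.loc[sample_t, "condition"]
    return out[["gene", "condition", "sample", "generations", "F", "n_mutants"]]


def significance_call(
    scores: pd.DataFrame,
    threshold: float = F_THRESHOLD,
    min_generations: float = MIN_GENERATIONS,
) -> pd.DataFrame:
    """Flag significant fitness effects: |F| >= threshold (boundary inclusive)
    after at least ``min_generations`` generations."""
    out = scores.copy()
    out["significant"] = (out["F"].abs() >= threshold) & (
        out["generations"] >= min_generations
    )
    return out


def fitness_scores(
    counts: BarcodeCounts,
    pseudocount: float = PSEUDOCOUNT,
    threshold: float = F_THRESHOLD,
    min_generations: float = MIN_GENERATIONS,
    neutral_genes: list[str] | None = None,
    weighting: str = "inverse_variance",
) -> pd.DataFrame:
    """Gene fitness for every post-selection sample against its generation-0
    reference, with significance calls."""
    meta = counts.samples
    frames = []
    for (cond, rep), grp in meta.groupby(["condition", "replicate"]):
        t0_rows = grp[grp["generations"] == 0]
        if t0_rows.empty:
            raise ValueError(f"no generation-0 sample for {cond} replicate {rep}")
        t0 = t0_rows["sample"].iloc[0]
        for _, row in grp[grp["generations"] > 0].iterrows():
            frames.append(gene_fitness(
                counts, t0, row["sample"], pseudocount=pseudocount,
                neutral_genes=neutral_genes, weighting=weighting,
            ))
    scores = pd.concat(frames, ignore_index=True)
    return significance_call(scores, threshold, min_generations)
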