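"""Correspondence analysis of per-gene RSCU profiles.

Genes are placed in the 59-dimensional space of synonymous-codon RSCU
values and decomposed by classical correspondence analysis: the table is
normalised to proportions P, the standardised residual matrix
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is factored by SVD, and genes and
codons are mapped to principal coordinates.  Axis k explains
sigma_k^2 / sum(sigma^2) of the total inertia.

The SVD leaves each axis's sign arbitrary; when a per-gene orientation
vector (conventionally GC3s) is supplied, axis 1 is flipped so its
correlation with that vector is non-negative, making coordinates
reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoaResult:
    gene_coords: pd.DataFrame       # genes x retained axes (principal coords)
    codon_coords: pd.DataFrame      # codons x retained axes
    inertia_pct: np.ndarray         # % of total inertia per axis, all axes
    total_inertia: float
    n_axes: int
    dropped_genes: list = field(default_factory=list)
    no_variation: bool = False


def correspondence_analysis(
    matrix: pd.DataFrame,
    n_axes: int = 4,
    orient_by: pd.Series | None = None,
) -> CoaResult:
    """Classical CA of a genes x codons RSCU (or count) matrix.

    All-zero rows are dropped and reported.  A matrix with no variation
    (all rows proportional) returns ``no_variation=True`` with empty
    coordinates instead of failing.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("CA input must be non-negative")
    row_sums = matrix.sum(axis=1)
    dropped = list(matrix.index[row_sums == 0])
    m = matrix.loc[row_sums > 0]
    if len(m) < 5:
        raise ValueError("CA needs at least 5 genes with nonzero usage")

    x = m.to_numpy(dtype=float)
    n = x.sum()
    p = x / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep_cols = c > 0
    p = p[:, keep_cols]
    c = c[keep_cols]
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))

    u, sigma, vt = np.linalg.svd(s, full_matrices=False)
    total_inertia = float((sigma ** 2).sum())
    if total_inertia < 1e-12:
        return CoaResult(
            gene_coords=pd.DataFrame(index=m.index),
            codon_coords=pd.DataFrame(index=m.columns[keep_cols]),
            inertia_pct=np.zeros(0),
            total_inertia=0.0,
            n_axes=0,
            dropped_genes=dropped,
            no_variation=True,
        )

    rank = int((sigma > 1e-12 * sigma[0]).sum())
    if rank < 2:
        raise ValueError("degenerate CA input (rank < 2)")
    k = min(n_axes, rank)
    inertia_pct = sigma[:rank] ** 2 / total_inertia * 100.0

    # principal coordinates: rows F = D_r^{-1/2} U Sigma, cols G = D_c^{-1/2} V Sigma
    f = u[:, :k] * sigma[:k] / np.sqrt(r)[:, None]
    g = vt[:k].T * sigma[:k] / np.sqrt(c)[:, None]

    if orient_by is not None:
        ref = orient_by.reindex(m.index).to_numpy(dtype=float)
        ok = ~np.isnan(ref)
        for ax in range(k):
            if ok.sum() >= 3 and np.corrcoef(f[ok, ax], ref[ok])[0, 1] < 0:
                f[:, ax] *= -1
                g[:, ax] *= -1

    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        gene_coords=pd.DataFrame(f, index=m.index, columns=axes),
        codon_coords=pd.DataFrame(g, index=m.columns[keep_cols], columns=axes),
        inertia_pct=inertia_pct,
        total_inertia=total_inertia,
        n_axes=k,
        dropped_genes=dropped,
    )


def axis_trait_correlations(
    coa: CoaResult,
    table: pd.DataFrame,
    traits: list[str] = ("gc", "gc3s", "enc", "cai", "cbi", "fop"),
    axis: str = "axis1",
) -> pd.DataFrame:
    """Pearson correlation of one CA axis with CUB indices, per trait."""
    missing = [g for g in coa.gene_coords.index if g not in table.index]
    if missing:
        raise ValueError(f"genes absent from index table: {missing[:5]}...")
    coords = coa.gene_coords[axis]
    rows = []
    for trait in traits:
        if trait not in table.columns:
            continue
        sub = pd.concat([coords, table.loc[coords.index, trait]], axis=1).dropna()
        if len(sub) < 3 or sub[trait].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sub[axis], sub[trait])
        rows.append({"trait": trait, "r": r, "p": p,
                     "sig_05": p < 0.05 if p == p else False,
                     "sig_01": p < 0.01 if p == p else False})
    return pd.DataFrame(rows)
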