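"""Codon-pair context analysis.

Adjacent codon pairs (5' codon, 3' codon) are accumulated into a 64 x 64
contingency table, stop codons included so the 5'-context of termination
can be profiled.  Departures from pair-independence are scored with
adjusted (Haberman) residuals

    z_ij = (o_ij - e_ij) / sqrt(e_ij (1 - r_i/N)(1 - c_j/N)),

approximately standard normal under independence; pairs with z above a
threshold (default 3.0, ~p < 0.003 two-sided) are called *preferred*,
below the negative threshold *avoided*.  Per-genome residual matrices,
flattened to 4096-vectors, support a correlation-distance hierarchical
clustering of context patterns across genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genetic_code import ALL_CODONS, GeneticCode, bacterial_code, to_rna
from .seq_ingest import CodingSequence

START_CODON = "ATG"


@dataclass
class PairCountMatrix:
    counts: pd.DataFrame  # 64 x 64, rows = 5' codon, cols = 3' codon
    genome: str = ""
    n_flagged_no_stop: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_pair_types(self) -> int:
        """Number of distinct pairs observed (nonzero cells)."""
        return int((self.counts.to_numpy() > 0).sum())


@dataclass
class ResidualMatrix:
    residuals: pd.DataFrame   # adjusted residuals; NaN where undefined
    expected: pd.DataFrame
    calls: pd.DataFrame       # 'preferred' | 'avoided' | 'neutral' | 'undefined'
    threshold: float


def count_codon_pairs(
    seqs: list[CodingSequence],
    code: GeneticCode | None = None,
    genome: str = "",
) -> PairCountMatrix:
    """Accumulate ordered adjacent codon pairs over genes, stop included.

    A gene of L codons contributes L - 1 pairs; self-pairs count.  Genes
    lacking a terminal stop still contribute their sense-codon pairs and
    are tallied in ``n_flagged_no_stop``.
    """
    code = code or bacterial_code()
    mat = np.zeros((64, 64), dtype=np.int64)
    idx = {c: i for i, c in enumerate(ALL_CODONS)}
    flagged = 0
    for s in seqs:
        codons = [s.seq[i : i + 3] for i in range(0, len(s.seq) - len(s.seq) % 3, 3)]
        if not codons or codons[-1] not in code.stop_codons:
            flagged += 1
        for a, b in zip(codons, codons[1:]):
            ia, ib = idx.get(a), idx.get(b)
            if ia is not None and ib is not None:
                mat[ia, ib] += 1
    df = pd.DataFrame(mat, index=ALL_CODONS, columns=ALL_CODONS)
    return PairCountMatrix(counts=df, genome=genome, n_flagged_no_stop=flagged)


def context_residuals(
    matrix: PairCountMatrix, threshold: float = 3.0
) -> ResidualMatrix:
    """Adjusted residuals of the pair table against row/column independence."""
    o = matrix.counts.to_numpy(dtype=float)
    n = o.sum()
    if n < 1000:
        warnings.warn(f"only {int(n)} pairs; residuals will be unstable")
    r = o.sum(axis=1)
    c = o.sum(axis=0)
    e = np.outer(r, c) / n
    denom = np.sqrt(e * np.outer(1 - r / n, 1 - c / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (o - e) / denom, np.nan)
    calls = np.full(z.shape, "neutral", dtype=object)
    calls[np.isnan(z)] = "undefined"
    calls[np.nan_to_num(z) > threshold] = "preferred"
    calls[np.nan_to_num(z) < -threshold] = "avoided"
    labels = matrix.counts.index
    return ResidualMatrix(
        residuals=pd.DataFrame(z, index=labels, columns=labels),
        expected=pd.DataFrame(e, index=labels, columns=labels),
        calls=pd.DataFrame(calls, index=labels, columns=labels),
        threshold=threshold,
    )


@dataclass
class ContextReport:
    start_most_used_3p: str | None
    start_most_avoided_3p: str | None
    stop_contexts: dict = field(default_factory=dict)
    top_pairs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"signal": "AUG (3' context)",
                 "most_used": self.start_most_used_3p,
                 "most_avoided": self.start_most_avoided_3p}]
        for stop, d in self.stop_contexts.items():
            rows.append({"signal": f"{stop} (5' context)",
                         "most_used": d["most_used"],
                         "most_avoided": d["most_avoided"]})
        return pd.DataFrame(rows)


def start_stop_context(
    matrix: PairCountMatrix,
    residuals: ResidualMatrix,
    code: GeneticCode | None = None,
    top_n: int = 10,
) -> ContextReport:
    """Most-used / most-avoided neighbours of start and stop codons.

    "Most used" is by raw pair count; "most avoided" is by the most
    negative adjusted residual.  Codon labels are reported in the RNA
    alphabet (AUG, UAA, UAG, UGA).  A stop codon no gene uses is marked
    not-applicable (None).
    """
    code = code or bacterial_code()
    counts, z = matrix.counts, residuals.residuals

    start_row = counts.loc[START_CODON]
    start_z = z.loc[START_CODON]
    has_start = start_row.sum() > 0
    most_used = to_rna(start_row.idxmax()) if has_start else None
    most_avoided = (
        to_rna(start_z.idxmin()) if has_start and start_z.notna().any() else None
    )

    stop_contexts = {}
    for stop in sorted(code.stop_codons):
        col = counts[stop]
        if col.sum() == 0:
            stop_contexts[to_rna(stop)] = {"most_used": None, "most_avoided": None}
            continue
        zcol = z[stop]
        stop_contexts[to_rna(stop)] = {
            "most_used": to_rna(col.idxmax()),
            "most_avoided": to_rna(zcol.idxmin()) if zcol.notna().any() else None,
        }

    flat = counts.stack()
    zflat = z.stack(future_stack=True)
    order = pd.DataFrame({"count": flat, "residual": zflat}).sort_values(
        ["count", "residual"], ascending=False
    )
    top_pairs = [
        (to_rna(a), to_rna(b), int(row["count"]), float(row["residual"]))
        for (a, b), row in order.head(top_n).iterrows()
    ]
    return ContextReport(
        start_most_used_3p=most_used,
        start_most_avoided_3p=most_avoided,
        stop_contexts=stop_contexts,
        top_pairs=top_pairs,
    )


def context_distance_matrix(residuals: dict[str, ResidualMatrix]) -> pd.DataFrame:
    """1 - Pearson correlation between flattened residual vectors (NaN -> 0)."""
    genomes = list(residuals)
    vecs = np.vstack([
        np.nan_to_num(residuals[g].residuals.to_numpy().ravel()) for g in genomes
    ])
    corr = np.corrcoef(vecs)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return pd.DataFrame(d, index=genomes, columns=genomes)


def cluster_contexts(residuals: dict[str, ResidualMatrix]):
    """Average-linkage hierarchical clustering of genome context patterns.

    Returns the scipy linkage matrix and the genome label order.
    """
    if len(residuals) < 3:
        raise ValueError("context clustering needs at least 3 genomes")
    dist = context_distance_matrix(residuals)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    return link, list(dist.index)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    def walk_root(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:0;"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right});"

    return walk_root(tree)
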