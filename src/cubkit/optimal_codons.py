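"""Optimal-codon identification from expression extremes.

Genes are ranked by CAI; the top and bottom fractions (default 5%) stand
in for high- and low-expression gene sets.  RSCU is computed on the
aggregated codon counts of each set, and the difference
dRSCU = RSCU_high - RSCU_low drives the classification:

* **optimal codon** — dRSCU > 0.08 and high-set RSCU > 1 (strict);
* **high-frequency codon** — genome-wide RSCU > 1.

The two flags are computed independently; an optimal codon need not be
high-frequency and vice versa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .genetic_code import GeneticCode, bacterial_code
from .indices import rscu
from .seq_ingest import CodonCountTable

DELTA_RSCU_THRESHOLD = 0.08


@dataclass
class ExpressionExtremes:
    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    fraction: float
    high_cai_cutoff: float
    low_cai_cutoff: float
    ties_broken: bool


def expression_extremes(
    table: pd.DataFrame, fraction: float = 0.05
) -> ExpressionExtremes:
    """Top and bottom ``fraction`` of genes by CAI; ties broken by gene id."""
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    sub = table["cai"].dropna()
    n = len(sub)
    if n < 20:
        warnings.warn(f"only {n} genes; expression extremes will be noisy")
    k = max(1, math.floor(fraction * n))
    ranked = sub.reset_index().sort_values(
        ["cai", "gene_id"], ascending=[False, True]
    )
    high = ranked.head(k)
    low = sub.reset_index().sort_values(
        ["cai", "gene_id"], ascending=[True, True]
    ).head(k)
    ties = sub.duplicated().any()
    if ties and sub.nunique() == 1:
        warnings.warn("all CAI values identical; extremes set by id order only")
    return ExpressionExtremes(
        high_ids=tuple(high["gene_id"]),
        low_ids=tuple(low["gene_id"]),
        fraction=fraction,
        high_cai_cutoff=float(high["cai"].min()),
        low_cai_cutoff=float(low["cai"].max()),
        ties_broken=bool(ties),
    )


def delta_rscu(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    genome_counts: CodonCountTable,
    code: GeneticCode | None = None,
    threshold: float = DELTA_RSCU_THRESHOLD,
    rscu_reference: str = "high",
) -> pd.DataFrame:
    """Per-codon RSCU in the high/low sets, dRSCU, and classification flags.

    ``rscu_reference`` selects which RSCU the "RSCU > 1" clause of the
    optimal-codon rule is tested against: the high-expression set
    (default) or the whole genome.
    """
    code = code or bacterial_code()
    for t, name in ((high_counts, "high"), (low_counts, "low"),
                    (genome_counts, "genome")):
        if t.total == 0:
            raise ValueError(f"{name} count table is empty")
    df = pd.DataFrame({
        "rscu_high": rscu(high_counts, code),
        "rscu_low": rscu(low_counts, code),
        "rscu_genome": rscu(genome_counts, code),
    })
    df["delta_rscu"] = df["rscu_high"] - df["rscu_low"]
    df["amino_acid"] = [code.codon_to_aa[c] for c in df.index]
    ref = df["rscu_high"] if rscu_reference == "high" else df["rscu_genome"]
    df["optimal"] = (df["delta_rscu"] > threshold) & (ref > 1.0)
    df["high_frequency"] = df["rscu_genome"] > 1.0
    return df


def compare_codon_sets(
    tables: dict[str, pd.DataFrame], which: str = "optimal"
) -> tuple[pd.DataFrame, dict]:
    """Cross-genome presence/absence of optimal (or high-frequency) codons.

    Returns the membership matrix (codons x genomes, bool) and a summary
    with the codons shared by every genome plus their ending-base tally.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 genomes to compare")
    membership = pd.DataFrame({
        genome: df[which] for genome, df in tables.items()
    }).fillna(False)
    shared = membership.index[membership.all(axis=1)]
    at_ending = sum(1 for c in shared if c[2] in "AT")
    gc_ending = len(shared) - at_ending
    summary = {
        "shared_codons": sorted(shared),
        "n_shared": len(shared),
        "shared_at_ending": at_ending,
        "shared_gc_ending": gc_ending,
        "per_genome_counts": membership.sum().to_dict(),
    }
    return membership, summary
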