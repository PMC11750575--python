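"""Nucleotide-composition and codon-usage-bias indices.

Per gene (or per genome aggregate) this module computes:

* positional G+C content GC1/GC2/GC3, their mean GC12, and GC3s (G+C at
  third positions of synonymous codons only, i.e. excluding Met, Trp and
  stops);
* third-position base counts A3/T3/G3/C3 over sense codons;
* RSCU — observed codon count over its expected count under uniform usage
  within its synonymous family;
* CAI — geometric mean of relative-adaptiveness weights w derived from a
  highly expressed reference gene set (w = RSCU / max family RSCU);
* ENC — Wright's effective number of codons, from family homozygosities
  F = (n * sum(p^2) - 1) / (n - 1) averaged within degeneracy classes:
  ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, in [20, 61];
* CBI and FOP against a supplied optimal-codon set;
* GRAVY (mean Kyte-Doolittle hydropathy) and AROMO (aromatic fraction).

All internal fractions are on [0, 1]; report writers multiply by 100.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import AROMATIC, KYTE_DOOLITTLE, GeneticCode, bacterial_code
from .seq_ingest import CodingSequence, CodonCountTable, count_codons

RIBOSOMAL_REGEX = r"ribosomal[\s_-]+protein|\brps[A-Z]\b|\brpl[A-Z]\b|\brpm[A-Z]\b"


@dataclass
class CompositionRecord:
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    gc: float
    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def composition(counts: CodonCountTable, code: GeneticCode | None = None) -> CompositionRecord:
    """Positional base composition from codon identities weighted by counts."""
    code = code or bacterial_code()
    pos_gc = [0, 0, 0]
    n_sense = 0
    third: dict[str, int] = {"A": 0, "T": 0, "G": 0, "C": 0}
    syn_gc3 = 0
    n_syn = 0
    for codon, n in counts.counts.items():
        if codon not in code.codon_to_aa or n == 0:
            continue
        n_sense += n
        for i, base in enumerate(codon):
            if base in "GC":
                pos_gc[i] += n
        third[codon[2]] += n
        if code.degeneracy(codon) >= 2:
            n_syn += n
            if codon[2] in "GC":
                syn_gc3 += n
    if n_sense == 0:
        raise ValueError("no sense codons in count table")
    return CompositionRecord(
        gc1=pos_gc[0] / n_sense,
        gc2=pos_gc[1] / n_sense,
        gc3=pos_gc[2] / n_sense,
        gc3s=syn_gc3 / n_syn if n_syn else float("nan"),
        gc=sum(pos_gc) / (3 * n_sense),
        a3=third["A"],
        t3=third["T"],
        g3=third["G"],
        c3=third["C"],
    )


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> pd.Series:
    """RSCU over the 59 synonymous sense codons (Met, Trp, stops excluded).

    Families with zero total count get RSCU 0 for every member (the family
    is simply absent from the gene); uniform usage gives 1 per codon.
    """
    code = code or bacterial_code()
    out: dict[str, float] = {}
    for family in code.families.values():
        if len(family) == 1:
            continue
        total = sum(counts[c] for c in family)
        if total == 0:
            for c in family:
                out[c] = 0.0
        else:
            expected = total / len(family)
            for c in family:
                out[c] = counts[c] / expected
    return pd.Series(out).reindex(code.synonymous_codons)


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w per synonymous codon, max 1 within each family."""

    w: pd.Series
    provenance: str = ""
    reference_ids: tuple[str, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return float(self.w[codon])


def weights_from_counts(
    counts: CodonCountTable,
    code: GeneticCode | None = None,
    pseudo_weight: float = 0.01,
    provenance: str = "",
    reference_ids: tuple[str, ...] = (),
) -> ReferenceWeights:
    """w_j = RSCU_j / max(RSCU in family); zero-usage codons get the pseudo-weight."""
    code = code or bacterial_code()
    r = rscu(counts, code)
    w = pd.Series(index=r.index, dtype=float)
    for family in code.families.values():
        if len(family) == 1:
            continue
        fam = r[list(family)]
        m = fam.max()
        if m <= 0:
            w[list(family)] = 1.0  # absent family: neutral, never scored anyway
        else:
            w[list(family)] = (fam / m).clip(lower=pseudo_weight)
    w[w <= 0] = pseudo_weight
    return ReferenceWeights(w=w, provenance=provenance, reference_ids=reference_ids)


def build_reference_weights(
    seqs: list[CodingSequence],
    selector: str = "annotation-pattern",
    pattern: str = RIBOSOMAL_REGEX,
    id_list: list[str] | None = None,
    top_fraction: float = 0.05,
    code: GeneticCode | None = None,
    pseudo_weight: float = 0.01,
) -> ReferenceWeights:
    """Build CAI weights from a highly-expressed reference gene set.

    selector:
      ``annotation-pattern`` — genes whose FASTA description matches
      ``pattern`` (default: ribosomal-protein annotations);
      ``explicit`` — genes named in ``id_list``;
      ``iterative`` — two passes: provisional CAI from genome-wide usage,
      then weights rebuilt from the top ``top_fraction`` of genes.
    """
    code = code or bacterial_code()
    if selector == "annotation-pattern":
        rx = re.compile(pattern, re.IGNORECASE)
        ref = [s for s in seqs if rx.search(s.description)]
        if not ref:
            raise ValueError(
                "annotation-pattern matched no genes; supply an explicit id list "
                "or use the iterative selector"
            )
    elif selector == "explicit":
        wanted = set(id_list or [])
        ref = [s for s in seqs if s.id in wanted]
        if not ref:
            raise ValueError("explicit reference id list matched no genes")
    elif selector == "iterative":
        genome = CodonCountTable.aggregate([count_codons(s, code=code) for s in seqs])
        provisional = weights_from_counts(genome, code, pseudo_weight)
        scored = sorted(
            seqs,
            key=lambda s: (-cai(count_codons(s, code=code), provisional, code), s.id),
        )
        k = max(1, math.floor(top_fraction * len(seqs)))
        ref = scored[:k]
    else:
        raise ValueError(f"unknown reference selector: {selector!r}")

    agg = CodonCountTable.aggregate(
        [count_codons(s, code=code) for s in ref], scope="gene_set"
    )
    return weights_from_counts(
        agg,
        code,
        pseudo_weight,
        provenance=f"{selector} (n={len(ref)})",
        reference_ids=tuple(s.id for s in ref),
    )


def cai(
    counts: CodonCountTable,
    weights: ReferenceWeights,
    code: GeneticCode | None = None,
) -> float:
    """Geometric mean of w over synonymous codons: exp(mean log w)."""
    code = code or bacterial_code()
    log_sum = 0.0
    n = 0
    for codon, k in counts.counts.items():
        if codon in weights.w.index and k > 0:
            log_sum += k * math.log(weights[codon])
            n += k
    if n == 0:
        raise ValueError("no scorable codons for CAI")
    return math.exp(log_sum / n)


def enc(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons on [20, 61].

    Families with total count < 2 or homozygosity F == 0 are uninformative
    and excluded from class means.  A missing 3-fold class is interpolated
    as the mean of the 2- and 4-fold means; other missing classes drop out
    and the sum is rescaled by the represented family fraction.
    """
    code = code or bacterial_code()
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for family in code.families.values():
        k = len(family)
        if k == 1:
            continue
        n = sum(counts[c] for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in family)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            class_F[k].append(f)

    means = {k: (np.mean(v) if v else None) for k, v in class_F.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2.0

    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    present = [k for k in (2, 3, 4, 6) if means[k] is not None]
    if not present:
        return float("nan")
    contrib = sum(n_families[k] / means[k] for k in present)
    covered = sum(n_families[k] for k in present)
    value = 2.0 + contrib * (18 / covered)
    return min(61.0, max(20.0, value))


def cbi(
    counts: CodonCountTable,
    optimal: set[str],
    code: GeneticCode | None = None,
) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran) over families
    holding an optimal codon; 1 = all optimal, 0 = uniform, negative = avoided."""
    code = code or bacterial_code()
    n_tot = n_opt = 0
    n_ran = 0.0
    for family in code.families.values():
        if len(family) == 1 or not (set(family) & optimal):
            continue
        fam_total = sum(counts[c] for c in family)
        n_tot += fam_total
        n_opt += sum(counts[c] for c in family if c in optimal)
        n_ran += fam_total / len(family)
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        return float("nan")
    return (n_opt - n_ran) / (n_tot - n_ran)


def fop(
    counts: CodonCountTable,
    optimal: set[str],
    code: GeneticCode | None = None,
) -> float:
    """Frequency of optimal codons among synonymous codons of covered families."""
    code = code or bacterial_code()
    n_tot = n_opt = 0
    for family in code.families.values():
        if len(family) == 1 or not (set(family) & optimal):
            continue
        n_tot += sum(counts[c] for c in family)
        n_opt += sum(counts[c] for c in family if c in optimal)
    if n_tot == 0:
        return float("nan")
    return n_opt / n_tot


def gravy(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Count-weighted mean Kyte-Doolittle hydropathy of the encoded residues."""
    code = code or bacterial_code()
    total = score = 0
    for codon, n in counts.counts.items():
        aa = code.codon_to_aa.get(codon)
        if aa is not None and n > 0:
            score += n * KYTE_DOOLITTLE[aa]
            total += n
    if total == 0:
        raise ValueError("no sense codons for GRAVY")
    return score / total


def aromo(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Fraction of encoded residues that are aromatic (Phe, Tyr, Trp)."""
    code = code or bacterial_code()
    total = arom = 0
    for codon, n in counts.counts.items():
        aa = code.codon_to_aa.get(codon)
        if aa is not None and n > 0:
            total += n
            if aa in AROMATIC:
                arom += n
    if total == 0:
        raise ValueError("no sense codons for AROMO")
    return arom / total


INDEX_COLUMNS = [
    "gene_id", "genome", "length_codons", "cai", "cbi", "fop",
    "gravy", "aromo", "enc", "gc1", "gc2", "gc3", "gc12", "gc3s", "gc",
    "a3", "t3", "g3", "c3", "short_gene",
]


def gene_index_table(
    seqs: list[CodingSequence],
    weights: ReferenceWeights,
    optimal: set[str] | None = None,
    code: GeneticCode | None = None,
    short_gene_codons: int = 100,
) -> pd.DataFrame:
    """One row per gene joining composition and CUB indices (Table-2 analog).

    CBI/FOP columns are NaN until an optimal-codon set is supplied (the
    pipeline fills them after optimal-codon identification).
    """
    code = code or bacterial_code()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in seqs:
            counts = count_codons(s, include_stop=False, code=code)
            comp = composition(counts, code)
            n_codons = counts.sense_total(code)
            rows.append({
                "gene_id": s.id,
                "genome": s.genome,
                "length_codons": n_codons,
                "cai": cai(counts, weights, code),
                "cbi": cbi(counts, optimal, code) if optimal else float("nan"),
                "fop": fop(counts, optimal, code) if optimal else float("nan"),
                "gravy": gravy(counts, code),
                "aromo": aromo(counts, code),
                "enc": enc(counts, code),
                "gc1": comp.gc1, "gc2": comp.gc2, "gc3": comp.gc3,
                "gc12": comp.gc12, "gc3s": comp.gc3s, "gc": comp.gc,
                "a3": comp.a3, "t3": comp.t3, "g3": comp.g3, "c3": comp.c3,
                "short_gene": n_codons < short_gene_codons,
            })
    return pd.DataFrame(rows, columns=INDEX_COLUMNS).set_index("gene_id")


def genome_summary(table: pd.DataFrame) -> pd.Series:
    """Per-genome means of the numeric index columns."""
    numeric = table.select_dtypes("number")
    return numeric.mean()
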