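"""Truth-annotated synthetic CDS genomes under a mutation-selection codon model.

Each synthetic gene carries a mutational GC bias theta_g (the chance a
freely mutating site is G or C) and an expression level e_g; a genome
carries a planted optimal-codon set O (one codon per synonymous family)
and a selection strength s.  Codons are drawn per gene according to the
mode:

* ``mutation`` — codon probability proportional to the product of base
  weights over its three positions (G, C each theta_g/2; A, T each
  (1 - theta_g)/2), restricted to sense codons.  Amino-acid usage thus
  co-varies with theta_g, which is exactly what makes the neutrality
  slope approach 1.
* ``selection`` — amino acids drawn from a fixed background; within each
  family the synonymous codon probability is proportional to
  exp(s * e_g * [codon in O]) times the third-base mutational weight at a
  genome-constant theta.  Amino-acid (hence GC12) usage stays flat while
  silent sites respond to selection, driving the neutrality slope to 0.
* ``mixed`` — the selection sampler with per-gene theta_g.

Genes start with ATG and end with one sampled stop codon.  Optionally a
set of context pairs is planted: during sequential codon sampling the
probability of the next codon is boosted by exp(context_strength) when
(previous, next) is a planted pair, giving genomes a codon-pair signature
independent of their single-codon usage.

Identical spec + seed reproduce identical FASTA bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import ALL_CODONS, GeneticCode, bacterial_code

# Background amino-acid frequencies for selection/mixed modes: a smoothed
# average bacterial proteome composition (order fixed for reproducibility).
BACKGROUND_AA = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.011,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.021, "I": 0.060,
    "L": 0.105, "K": 0.047, "M": 0.023, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.013, "Y": 0.029, "V": 0.070,
}


def default_optimal_set(code: GeneticCode | None = None) -> frozenset[str]:
    """One planted preferred codon per family with degeneracy >= 2.

    C-ending codons are used where the family has one (mimicking the
    G/C-ending preference of thermophile genomes), otherwise the G-ending
    codon, otherwise the lexicographically first member.
    """
    code = code or bacterial_code()
    chosen = []
    for family in code.families.values():
        if len(family) == 1:
            continue
        by_end = {c[2]: c for c in sorted(family)}
        chosen.append(by_end.get("C") or by_end.get("G") or sorted(family)[0])
    return frozenset(chosen)


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic genome, with recorded truth."""

    name: str = "custom"
    n_genes: int = 500
    mean_length: float = 300.0       # codons, lognormal location
    length_sigma: float = 0.35       # lognormal shape
    theta_alpha: float = 2.0         # per-gene GC bias ~ Beta(alpha, beta)
    theta_beta: float = 2.0
    theta_fixed: float | None = None  # overrides the Beta draw when set
    expression_rate: float = 1.0      # e_g ~ Exponential(rate)
    selection: float = 0.0            # s >= 0
    mode: str = "mutation"            # mutation | selection | mixed
    optimal_set: frozenset[str] = field(default_factory=default_optimal_set)
    stop_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)  # TAA, TAG, TGA
    context_pairs: frozenset[tuple[str, str]] = frozenset()
    context_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"mutation", "selection", "mixed"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.selection < 0:
            raise ValueError("selection strength must be >= 0")
        if self.theta_alpha <= 0 or self.theta_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.expression_rate <= 0:
            raise ValueError("expression rate must be positive")
        code = bacterial_code()
        fams = set()
        for c in self.optimal_set:
            fam = code.family_of(c)
            if fam in fams:
                raise ValueError("optimal set has two codons in one family")
            fams.add(fam)

    def to_json(self) -> str:
        d = asdict(self)
        d["optimal_set"] = sorted(self.optimal_set)
        d["context_pairs"] = sorted(map(list, self.context_pairs))
        return json.dumps(d, indent=2)


def _mutation_codon_probs(theta: float, code: GeneticCode) -> np.ndarray:
    """P(codon) over the 61 sense codons under independent per-base GC bias."""
    base_w = {"G": theta / 2, "C": theta / 2, "A": (1 - theta) / 2, "T": (1 - theta) / 2}
    probs = np.array([
        math.prod(base_w[b] for b in c) if c in code.codon_to_aa else 0.0
        for c in ALL_CODONS
    ])
    return probs / probs.sum()


def _selection_codon_probs(
    theta: float, s_times_e: float, optimal: frozenset[str], code: GeneticCode
) -> np.ndarray:
    """P(codon) = P(aa) * P(codon | aa) with selection on the planted set."""
    base_w = {"G": theta / 2, "C": theta / 2, "A": (1 - theta) / 2, "T": (1 - theta) / 2}
    s_times_e = min(s_times_e, 700.0)  # exp() overflow guard; already fixation
    probs = np.zeros(64)
    idx = {c: i for i, c in enumerate(ALL_CODONS)}
    for aa, family in code.families.items():
        weights = np.array([
            math.exp(s_times_e) if c in optimal else 1.0 for c in family
        ]) * np.array([base_w[c[2]] for c in family])
        weights /= weights.sum()
        for c, w in zip(family, weights):
            probs[idx[c]] = BACKGROUND_AA[aa] * w
    return probs / probs.sum()


def _sample_gene(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    spec: SyntheticSpec,
) -> list[str]:
    """Draw `length` body codons, optionally with planted pair enrichment."""
    if not spec.context_pairs or spec.context_strength == 0.0:
        draws = rng.choice(64, size=length, p=probs)
        return [ALL_CODONS[i] for i in draws]
    boost = math.exp(spec.context_strength)
    followers: dict[str, set[str]] = {}
    for a, b in spec.context_pairs:
        followers.setdefault(a, set()).add(b)
    codons: list[str] = []
    prev = "ATG"  # the start codon precedes the first body codon
    for _ in range(length):
        fset = followers.get(prev)
        if fset:
            p = probs.copy()
            for b in fset:
                p[ALL_CODONS.index(b)] *= boost
            p /= p.sum()
        else:
            p = probs
        nxt = ALL_CODONS[rng.choice(64, p=p)]
        codons.append(nxt)
        prev = nxt
    return codons


def generate_genome(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate one genome: list of (gene id, CDS string) plus the truth table.

    Every gene is ATG + body codons + one stop; the truth table records
    theta_g, e_g, length and mode per gene.
    """
    code = code or bacterial_code()
    rng = np.random.default_rng(spec.seed)
    stops = ("TAA", "TAG", "TGA")
    stop_p = np.array(spec.stop_weights, dtype=float)
    stop_p /= stop_p.sum()

    records: list[tuple[str, str]] = []
    truth_rows = []
    for g in range(spec.n_genes):
        if spec.theta_fixed is not None and spec.mode != "mixed":
            theta = spec.theta_fixed
        else:
            theta = float(rng.beta(spec.theta_alpha, spec.theta_beta))
            # keep silent sites away from fixation so indices stay defined
            theta = min(max(theta, 0.02), 0.98)
        e = float(rng.exponential(1.0 / spec.expression_rate))
        length = max(30, int(round(rng.lognormal(
            math.log(spec.mean_length), spec.length_sigma
        ))))

        if spec.mode == "mutation":
            probs = _mutation_codon_probs(theta, code)
        else:
            t = spec.theta_fixed if (
                spec.mode == "selection" and spec.theta_fixed is not None
            ) else theta
            probs = _selection_codon_probs(t, spec.selection * e, spec.optimal_set, code)

        body = _sample_gene(rng, length, probs, spec)
        stop = stops[rng.choice(3, p=stop_p)]
        gene_id = f"{spec.name}_g{g:05d}"
        records.append((gene_id, "ATG" + "".join(body) + stop))
        truth_rows.append({
            "gene_id": gene_id, "theta": theta, "expression": e,
            "length_codons": length + 2, "mode": spec.mode,
        })
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    truth.attrs["optimal_set"] = sorted(spec.optimal_set)
    truth.attrs["selection"] = spec.selection
    return records, truth


def write_genome(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit FASTA + truth TSV + spec JSON for one synthetic genome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate_genome(spec)
    fasta = out / f"{spec.name}.fasta"
    with open(fasta, "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id} synthetic {spec.mode}-mode gene\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    truth_path = out / f"{spec.name}.truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    spec_path = out / f"{spec.name}.spec.json"
    spec_path.write_text(spec.to_json())
    return fasta, truth_path, spec_path


def preset_suite(seed: int = 0, n_genes: int = 500) -> dict[str, SyntheticSpec]:
    """Named study conditions spanning the mutation-selection spectrum.

    * ``mutation-dominated`` — gene-specific GC bias (Beta(2,2)), no
      selection: neutrality slope near 1, genes on the ENC-GC3s curve.
    * ``selection-dominated`` — genome-constant theta = 0.5, selection
      s = 2 on the planted optimal set scaled by exponential expression:
      slope near 0, strong CAI gradient.
    * ``mixed`` — both forces at moderate strength.
    * ``null-uniform`` — theta = 0.5, no selection: RSCU = 1 everywhere
      up to sampling noise.
    """
    return {
        "mutation-dominated": SyntheticSpec(
            name="mutation-dominated", n_genes=n_genes,
            theta_alpha=2.0, theta_beta=2.0, selection=0.0,
            mode="mutation", seed=seed,
        ),
        "selection-dominated": SyntheticSpec(
            name="selection-dominated", n_genes=n_genes,
            theta_fixed=0.5, selection=2.0, expression_rate=1.0,
            mode="selection", seed=seed + 1,
        ),
        "mixed": SyntheticSpec(
            name="mixed", n_genes=n_genes,
            theta_alpha=5.0, theta_beta=5.0, selection=1.0,
            mode="mixed", seed=seed + 2,
        ),
        "null-uniform": SyntheticSpec(
            name="null-uniform", n_genes=n_genes,
            theta_fixed=0.5, selection=0.0,
            mode="selection", seed=seed + 3,
        ),
    }
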