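"""Reading, quality-filtering and codon-counting of coding sequences.

Input is one nucleotide CDS multi-FASTA per genome (optionally gzipped).
QC guarantees clean codon frames for the index calculations; it reports
failures rather than raising, so one bad annotation never aborts a run.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .genetic_code import ALL_CODONS, GeneticCode, bacterial_code

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
IUPAC_NUC = frozenset("ACGTRYSWKMBDHVN")


@dataclass
class CodingSequence:
    """A single CDS as read: id, upper-cased DNA sequence, source genome."""

    id: str
    seq: str
    genome: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class QCPolicy:
    """Toggleable CDS validation rules. Length % 3 == 0 is always enforced."""

    require_start: bool = True
    require_terminal_stop: bool = True
    forbid_internal_stop: bool = True
    forbid_ambiguous: bool = True
    min_codons: int = 30          # including the stop codon
    short_gene_codons: int = 100  # flag (not drop): ENC unstable below this
    ambiguous_mode: str = "discard"  # or "drop-codon"


@dataclass
class QCReport:
    """Per-gene pass/fail outcome with reasons; accounts for every input."""

    records: list[dict] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return sum(1 for r in self.records if r["passed"])

    @property
    def n_discarded(self) -> int:
        return len(self.records) - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.records, columns=["gene_id", "passed", "reasons", "flags"]
        )
        df["reasons"] = df["reasons"].map(";".join)
        df["flags"] = df["flags"].map(";".join)
        return df

    def summary(self) -> dict:
        return {
            "n_input": len(self.records),
            "n_retained": self.n_retained,
            "n_discarded": self.n_discarded,
        }


@dataclass
class CodonCountTable:
    """Counts of the 64 codons; scope is 'gene', 'gene_set' or 'genome'."""

    counts: Counter
    scope: str = "gene"
    label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def sense_total(self, code: GeneticCode) -> int:
        return sum(v for c, v in self.counts.items() if c in code.codon_to_aa)

    def to_series(self) -> pd.Series:
        return pd.Series({c: self.counts.get(c, 0) for c in ALL_CODONS})

    @staticmethod
    def aggregate(
        tables: "list[CodonCountTable]", scope: str = "genome", label: str = ""
    ) -> "CodonCountTable":
        total: Counter = Counter()
        for t in tables:
            total.update(t.counts)
        return CodonCountTable(total, scope=scope, label=label)


def read_cds_fasta(path: str | Path, genome: str | None = None) -> list[CodingSequence]:
    """Read a CDS multi-FASTA (plain or .gz) into :class:`CodingSequence` records.

    IDs are the first whitespace-delimited header token; sequences are
    upper-cased with U mapped to T.  Raises on unreadable or empty files;
    alphabet problems are left for QC.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = genome if genome is not None else path.name.split(".")[0]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [
            CodingSequence(
                id=rec.id,
                seq=str(rec.seq).upper().replace("U", "T"),
                genome=label,
                description=rec.description,
            )
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _check_one(
    seq: CodingSequence, policy: QCPolicy, code: GeneticCode
) -> tuple[list[str], list[str], str]:
    """Return (failure reasons, flags, possibly-cleaned sequence)."""
    reasons: list[str] = []
    flags: list[str] = []
    s = seq.seq

    bad_chars = set(s) - IUPAC_NUC
    if bad_chars:
        reasons.append("non-nucleotide characters")
        return reasons, flags, s
    if len(s) % 3 != 0:
        reasons.append("length not divisible by 3")
        return reasons, flags, s

    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    ambiguous = [c for c in codons if set(c) - set("ACGT")]
    if ambiguous and policy.forbid_ambiguous:
        if policy.ambiguous_mode == "drop-codon":
            codons = [c for c in codons if not set(c) - set("ACGT")]
            flags.append("ambiguous codons dropped")
            s = "".join(codons)
        else:
            reasons.append("ambiguous base")

    if len(codons) < policy.min_codons:
        reasons.append("below minimum codon count")
    if policy.require_start and (not codons or codons[0] not in START_CODONS):
        reasons.append("missing start")
    if policy.require_terminal_stop and (
        not codons or codons[-1] not in code.stop_codons
    ):
        reasons.append("missing terminal stop")
    if policy.forbid_internal_stop and any(
        c in code.stop_codons for c in codons[:-1]
    ):
        reasons.append("internal stop")

    n_sense = sum(1 for c in codons if c not in code.stop_codons)
    if n_sense < policy.short_gene_codons:
        flags.append("short gene")
    return reasons, flags, s


def qc_filter(
    seqs: list[CodingSequence],
    policy: QCPolicy | None = None,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], QCReport]:
    """Validate CDSs against the policy; failures are reported, never raised."""
    policy = policy or QCPolicy()
    code = code or bacterial_code()
    report = QCReport()
    retained: list[CodingSequence] = []
    for seq in seqs:
        reasons, flags, cleaned = _check_one(seq, policy, code)
        passed = not reasons
        report.records.append(
            {"gene_id": seq.id, "passed": passed, "reasons": reasons, "flags": flags}
        )
        if passed:
            if cleaned != seq.seq:
                seq = CodingSequence(seq.id, cleaned, seq.genome, seq.description)
            retained.append(seq)
    return retained, report


def count_codons(
    seq: CodingSequence | str,
    include_stop: bool = False,
    code: GeneticCode | None = None,
) -> CodonCountTable:
    """Count consecutive non-overlapping triplets from position 1.

    The terminal stop codon is included only when ``include_stop`` is set.
    """
    code = code or bacterial_code()
    s = seq if isinstance(seq, str) else seq.seq
    label = "" if isinstance(seq, str) else seq.id
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if not include_stop and codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    return CodonCountTable(Counter(codons), scope="gene", label=label)
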