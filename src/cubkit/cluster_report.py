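"""Genome-level RSCU clustering and end-to-end pipeline orchestration.

`run_pipeline` drives every stage for a set of genomes — QC, indices,
mutation-selection diagnostics, correspondence analysis, optimal codons,
codon-pair context — and writes TSV/Newick/JSON outputs plus a run
manifest.  Genome RSCU profiles (59-dimensional, from genome-aggregated
counts) are clustered with squared-Euclidean distance and between-groups
average linkage; context residual patterns are clustered separately.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import __version__
from .coa import axis_trait_correlations, correspondence_analysis
from .codon_context import (
    cluster_contexts,
    context_residuals,
    count_codon_pairs,
    linkage_to_newick,
    start_stop_context,
)
from .forces import enc_curve_points, index_correlations, neutrality_fit, pr2_points
from .genetic_code import bacterial_code
from .indices import (
    build_reference_weights,
    cbi,
    fop,
    gene_index_table,
    genome_summary,
    rscu,
)
from .optimal_codons import compare_codon_sets, delta_rscu, expression_extremes
from .seq_ingest import CodonCountTable, QCPolicy, count_codons, qc_filter, read_cds_fasta


@dataclass
class GenomeProfile:
    label: str
    rscu_vector: pd.Series  # 59 values from genome-aggregated counts
    mean_indices: pd.Series
    source: str = ""


def rscu_cluster(
    profiles: list[GenomeProfile], method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of genomes on their 59-dim RSCU vectors.

    Squared Euclidean distance with between-groups average linkage (the
    SPSS default pairing); ``method`` may be 'complete' or 'ward' instead.
    """
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels")
    if len(profiles) < 3:
        raise ValueError("clustering needs at least 3 genomes")
    x = np.vstack([p.rscu_vector.to_numpy() for p in profiles])
    d = pdist(x, metric="sqeuclidean")
    link = hierarchy.linkage(d, method=method)
    return link, labels


def _analyze_genome(seqs, label, cfg, code, out_dir: Path | None):
    """All per-genome stages; returns a dict of result objects."""
    res: dict = {"label": label}
    policy = cfg.get("qc_policy")
    if isinstance(policy, dict):
        policy = QCPolicy(**policy)
    retained, report = qc_filter(seqs, policy, code)
    res["qc"] = report
    if not retained:
        res["failed"] = "no genes passed QC"
        return res

    weights = build_reference_weights(
        retained,
        selector=cfg.get("reference_selector", "iterative"),
        id_list=cfg.get("reference_ids"),
        code=code,
    )
    table = gene_index_table(retained, weights, code=code)

    extremes = expression_extremes(table, cfg.get("expression_fraction", 0.05))
    per_gene = {s.id: count_codons(s, code=code) for s in retained}
    high = CodonCountTable.aggregate([per_gene[i] for i in extremes.high_ids], "gene_set")
    low = CodonCountTable.aggregate([per_gene[i] for i in extremes.low_ids], "gene_set")
    genome_counts = CodonCountTable.aggregate(list(per_gene.values()), "genome", label)
    drscu = delta_rscu(high, low, genome_counts, code)
    optimal = set(drscu.index[drscu["optimal"]])

    # fill CBI/FOP now that the genome's own optimal set is known
    if optimal:
        table["cbi"] = [cbi(per_gene[g], optimal, code) for g in table.index]
        table["fop"] = [fop(per_gene[g], optimal, code) for g in table.index]

    res["weights_provenance"] = weights.provenance
    res["table"] = table
    res["neutrality"] = neutrality_fit(table)
    res["enc_curve"] = enc_curve_points(table)
    res["pr2"], res["pr2_occupancy"] = pr2_points(table)
    res["correlations"] = index_correlations(table)

    rscu_matrix = pd.DataFrame(
        {s.id: rscu(per_gene[s.id], code) for s in retained}
    ).T
    coa_res = correspondence_analysis(rscu_matrix, orient_by=table["gc3s"])
    res["coa"] = coa_res
    if not coa_res.no_variation:
        res["axis_correlations"] = axis_trait_correlations(coa_res, table)

    res["delta_rscu"] = drscu
    res["extremes"] = extremes
    pairs = count_codon_pairs(retained, code, genome=label)
    residuals = context_residuals(pairs, cfg.get("residual_threshold", 3.0))
    res["pairs"] = pairs
    res["residuals"] = residuals
    res["context_report"] = start_stop_context(pairs, residuals, code)
    res["profile"] = GenomeProfile(
        label=label,
        rscu_vector=rscu(genome_counts, code),
        mean_indices=genome_summary(table),
        source=cfg.get("source", ""),
    )

    if out_dir is not None:
        g = out_dir / label
        g.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(g / "qc_report.tsv", sep="\t", index=False)
        (g / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2))
        table.to_csv(g / "gene_indices.tsv", sep="\t")
        _percent_summary(genome_summary(table)).to_csv(
            g / "genome_summary.tsv", sep="\t", header=["value"]
        )
        nf = res["neutrality"]
        pd.DataFrame([vars(nf)]).to_csv(g / "neutrality.tsv", sep="\t", index=False)
        res["enc_curve"].to_csv(g / "enc_gc3s.tsv", sep="\t")
        res["pr2"].to_csv(g / "pr2.tsv", sep="\t")
        res["pr2_occupancy"].to_csv(g / "pr2_quadrants.tsv", sep="\t", header=["fraction"])
        res["correlations"].to_csv(g / "index_correlations.tsv", sep="\t", index=False)
        if not coa_res.no_variation:
            coa_res.gene_coords.to_csv(g / "coa_gene_coords.tsv", sep="\t")
            coa_res.codon_coords.to_csv(g / "coa_codon_coords.tsv", sep="\t")
            pd.Series(
                coa_res.inertia_pct, name="inertia_pct",
                index=[f"axis{i+1}" for i in range(len(coa_res.inertia_pct))],
            ).to_csv(g / "coa_inertia.tsv", sep="\t")
            res["axis_correlations"].to_csv(
                g / "coa_axis1_correlations.tsv", sep="\t", index=False
            )
        drscu.to_csv(g / "delta_rscu.tsv", sep="\t")
        pairs.counts.to_csv(g / "pair_counts.tsv", sep="\t")
        residuals.residuals.to_csv(g / "pair_residuals.tsv", sep="\t")
        res["context_report"].to_frame().to_csv(
            g / "context_report.tsv", sep="\t", index=False
        )
    return res


def _percent_summary(means: pd.Series) -> pd.Series:
    """Genome summary with composition fractions also expressed as percent."""
    out = means.copy()
    for col in ("gc1", "gc2", "gc3", "gc12", "gc3s", "gc"):
        if col in out.index:
            out[f"{col}_pct"] = out[col] * 100.0
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute every stage for every genome listed in the config.

    ``config`` is a dict (or path to a YAML file) with at least
    ``genomes: {label: fasta_path}``; optional keys tune QC, the CAI
    reference selector, the expression fraction and the residual
    threshold.  Genomes that fail entirely are recorded in the manifest
    and skipped; the run is deterministic given the config.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = bacterial_code()
    genomes = config.get("genomes") or {}
    if not genomes:
        raise ValueError("config must list genomes: {label: fasta_path}")
    for label, path in genomes.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"genome {label!r}: FASTA not found at {path}")

    results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for label in sorted(genomes):
        seqs = read_cds_fasta(genomes[label], genome=label)
        res = _analyze_genome(seqs, label, config, code, out)
        if "failed" in res:
            failures[label] = res["failed"]
        else:
            results[label] = res

    bundle: dict = {"genomes": results, "failures": failures}
    if len(results) >= 2:
        membership, shared = compare_codon_sets(
            {g: r["delta_rscu"] for g, r in results.items()}, "optimal"
        )
        hf_membership, hf_shared = compare_codon_sets(
            {g: r["delta_rscu"] for g, r in results.items()}, "high_frequency"
        )
        membership.to_csv(out / "optimal_codon_membership.tsv", sep="\t")
        hf_membership.to_csv(out / "high_frequency_membership.tsv", sep="\t")
        (out / "codon_set_summary.json").write_text(
            json.dumps({"optimal": shared, "high_frequency": hf_shared}, indent=2)
        )
        bundle["optimal_shared"] = shared
        bundle["high_frequency_shared"] = hf_shared
    if len(results) >= 3:
        link, labels = rscu_cluster([r["profile"] for r in results.values()],
                                    config.get("linkage", "average"))
        rscu_newick = linkage_to_newick(link, labels)
        (out / "rscu_cluster.nwk").write_text(rscu_newick + "\n")
        clink, clabels = cluster_contexts({g: r["residuals"] for g, r in results.items()})
        ctx_newick = linkage_to_newick(clink, clabels)
        (out / "context_cluster.nwk").write_text(ctx_newick + "\n")
        bundle["rscu_newick"] = rscu_newick
        bundle["context_newick"] = ctx_newick

    manifest = {
        "cubkit_version": __version__,
        "python": platform.python_version(),
        "parameters": {
            k: v for k, v in config.items() if k not in ("genomes", "qc_policy")
        },
        "genomes_analyzed": sorted(results),
        "genomes_failed": failures,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
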