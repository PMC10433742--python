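"""End-to-end orchestration: discovery (normalize → cluster → collective tests
→ moderated t → enrichment → signature) and projection onto external cohorts,
with a machine-readable JSON run report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import clustering, differential, enrichment, normalization, signature as sig
from .io import TargetCollection
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    span: float = 0.4
    lowess_iterations: int = 3
    log2_input: bool = False  # True when the input is on linear intensity scale
    normalize: bool = True
    cut_fraction: float = 0.2
    cut_absolute: float | None = None
    min_size: int = 10
    alpha: float = 0.05
    fdr: float = 0.05
    fold: float = 2.0


@dataclass
class DiscoveryResult:
    normalized: ExpressionMatrix
    gene_tree: clustering.LinkageTree
    sample_tree: clustering.LinkageTree
    clusters: list[clustering.GeneCluster]
    differential_clusters: list[clustering.GeneCluster]
    tables: dict[tuple[str, str], differential.DifferentialTable]
    selections: dict[tuple[str, str], tuple[set, set]]
    signature: sig.Signature | None
    reduced_signature: sig.Signature | None
    enrichment_table: pd.DataFrame | None
    report: dict = field(default_factory=dict)


#: minimal report schema: required key -> type
REPORT_SCHEMA = {
    "n_genes": int,
    "n_samples": int,
    "n_clusters": int,
    "n_differential_clusters": int,
    "clusters": list,
    "differential": dict,
    "venn": dict,
    "signature_size": int,
    "reduced_signature_size": int,
}

PROJECTION_SCHEMA = {
    "n_samples": int,
    "match_rate": float,
    "n_matched_genes": int,
    "branch_sizes": dict,
    "n_up_in_LB": int,
    "n_down_in_LB": int,
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA) -> None:
    """Check required keys and types; raises on the first violation."""
    for key, typ in schema.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )


def _contrast_key(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def run_discovery(
    matrix: ExpressionMatrix,
    contrasts: list[tuple[str, str]],
    params: DiscoveryParams | None = None,
    terms: TargetCollection | None = None,
    shared_target_names: tuple[str, str] | None = None,
) -> DiscoveryResult:
    """Run the full signature-discovery chain on an expression matrix.

    ``contrasts`` are (treatment, control) group pairs; ``terms`` optionally
    supplies target lists for enrichment, and ``shared_target_names`` names the
    two lists whose shared targets define the reduced signature.
    """
    params = params or DiscoveryParams()
    stage = "normalization"
    try:
        normed = matrix
        if params.log2_input:
            normed = normalization.log2_and_center(normed, log=True, center="none")
        if params.normalize:
            normed = normalization.normalize_to_reference(
                normed, span=params.span, iterations=params.lowess_iterations
            )
        normed = normalization.log2_and_center(normed, log=False, center="median")

        stage = "clustering"
        gene_tree = clustering.average_linkage(normed, axis="genes")
        sample_tree = clustering.average_linkage(normed, axis="samples")
        clusters = clustering.cut_tree(
            gene_tree,
            fraction=params.cut_fraction,
            min_size=params.min_size,
            absolute=params.cut_absolute,
        )
        log.info("cut yielded %d clusters of size >= %d", len(clusters), params.min_size)

        stage = "collective tests"
        diff_clusters = clustering.extract_differential_clusters(
            normed, clusters, contrasts, alpha=params.alpha
        )
        log.info("%d clusters separate at least one contrast", len(diff_clusters))

        stage = "differential statistics"
        tables, selections = {}, {}
        for contrast in contrasts:
            table = differential.moderated_t_table(normed, *contrast)
            tables[contrast] = table
            selections[contrast] = differential.select_differential(
                table, params.fdr, params.fold
            )
        venn: dict[str, int] = {}
        if len(contrasts) >= 2:
            (upA, downA), (upB, downB) = (
                selections[contrasts[0]],
                selections[contrasts[1]],
            )
            venn = differential.venn_overlap(upA, downA, upB, downB)

        stage = "signature"
        signature_obj = reduced = None
        if diff_clusters:
            signature_obj = sig.build_signature(diff_clusters)
            if terms is not None and shared_target_names is not None:
                a, b = shared_target_names
                extra = {
                    name: members
                    for name, members in terms.sets.items()
                    if name not in (a, b)
                }
                reduced = sig.reduce_shared_targets(
                    signature_obj, terms.sets[a], terms.sets[b], extra_sets=extra
                )

        stage = "enrichment"
        enrich_table = None
        if terms is not None and diff_clusters:
            lists = {f"C{c.id}": set(c.members) for c in diff_clusters}
            chip = TargetCollection(
                dict(terms.sets), background=set(normed.gene_ids), descriptions=dict(terms.descriptions)
            )
            enrich_table = enrichment.enrich_many(lists, chip)
    except Exception as exc:
        raise RuntimeError(f"discovery failed at stage {stage!r}: {exc}") from exc

    report = {
        "n_genes": normed.n_genes,
        "n_samples": normed.n_samples,
        "n_clusters": len(clusters),
        "n_differential_clusters": len(diff_clusters),
        "clusters": [
            {
                "id": c.id,
                "size": c.size,
                "collective": {
                    _contrast_key(k): {
                        "t": r.t,
                        "p": r.p,
                        "direction": c.direction_pattern.get(k, "unchanged"),
                    }
                    for k, r in c.collective.items()
                },
            }
            for c in diff_clusters
        ],
        "differential": {
            _contrast_key(k): {"n_up": len(up), "n_down": len(down)}
            for k, (up, down) in selections.items()
        },
        "venn": venn,
        "signature_size": len(signature_obj) if signature_obj else 0,
        "reduced_signature_size": len(reduced) if reduced else 0,
    }
    validate_report(report)
    return DiscoveryResult(
        normalized=normed,
        gene_tree=gene_tree,
        sample_tree=sample_tree,
        clusters=clusters,
        differential_clusters=diff_clusters,
        tables=tables,
        selections=selections,
        signature=signature_obj,
        reduced_signature=reduced,
        enrichment_table=enrich_table,
        report=report,
    )


@dataclass
class ProjectionResult:
    classification: sig.BranchClassification
    up_in_LB: set
    down_in_LB: set
    table: differential.DifferentialTable
    report: dict


def run_projection(
    external_matrix: ExpressionMatrix,
    signature_obj: sig.Signature,
    exclude_samples=(),
    fdr: float = 0.01,
) -> ProjectionResult:
    """Project a signature onto an external cohort and compute branch statistics."""
    try:
        classification = sig.project_signature(
            external_matrix, signature_obj, exclude_samples
        )
        up, down, table = sig.branch_differential(
            external_matrix, classification, fdr_threshold=fdr
        )
    except Exception as exc:
        raise RuntimeError(f"projection failed: {exc}") from exc
    report = {
        "n_samples": external_matrix.n_samples,
        "match_rate": float(classification.match_rate),
        "n_matched_genes": len(classification.matched_genes),
        "branch_sizes": {
            "LB": len(classification.branch("LB")),
            "RB": len(classification.branch("RB")),
            "excluded": len(classification.branch("excluded")),
        },
        "n_up_in_LB": len(up),
        "n_down_in_LB": len(down),
    }
    validate_report(report, PROJECTION_SCHEMA)
    return ProjectionResult(classification, up, down, table, report)
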