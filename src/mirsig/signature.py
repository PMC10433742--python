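"""Signature construction, reduction to shared targets, and cohort projection.

A signature is the union of the differential co-expression clusters, with each
gene remembering its source cluster. Reducing it to the genes shared by two
target lists (e.g. targets of both miR mimics) yields the compact feature used
for projection: an external cohort is restricted to matched signature genes,
gene-median-centered, its samples clustered (uncentered Pearson, average
linkage), and the root bipartition of the sample dendrogram defines the left
and right branches (LB/RB). Branch-wise moderated-t statistics then run on the
whole transcriptome, not just the signature genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import GeneCluster, LinkageTree, average_linkage
from .differential import DifferentialTable, moderated_t_table, select_differential
from .matrix import ExpressionMatrix
from .normalization import log2_and_center

log = logging.getLogger(__name__)


@dataclass
class Signature:
    """Ordered gene list with per-gene source-cluster provenance."""

    genes: list[str]
    provenance: dict[str, int]
    reduction: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate genes")
        missing = [g for g in self.genes if g not in self.provenance]
        if missing:
            raise ValueError(f"provenance missing for {missing[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance and gene in set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "cluster": [self.provenance[g] for g in self.genes]}
        )


@dataclass
class BranchClassification:
    """Two-branch sample partition from the root of a sample dendrogram.

    Branch names are arbitrary: LB is the branch containing the first retained
    sample of the input matrix. Excluded samples are labelled "excluded".
    """

    labels: pd.Series  # sample -> "LB" / "RB" / "excluded"
    matched_genes: list[str]
    match_rate: float
    tree: LinkageTree

    def branch(self, name: str) -> list[str]:
        return list(self.labels.index[self.labels == name])


# ---------------------------------------------------------------------------


def build_signature(differential_clusters: list[GeneCluster]) -> Signature:
    """Union of cluster members, each tagged with its source cluster id."""
    if not differential_clusters:
        raise ValueError("no clusters supplied")
    genes: list[str] = []
    provenance: dict[str, int] = {}
    for cluster in differential_clusters:
        for gene in cluster.members:
            if gene in provenance:
                raise ValueError(
                    f"gene {gene!r} appears in clusters {provenance[gene]} and "
                    f"{cluster.id}; clusters from one cut must be disjoint"
                )
            provenance[gene] = cluster.id
            genes.append(gene)
    if not genes:
        raise ValueError("signature union is empty")
    return Signature(genes, provenance)


def reduce_shared_targets(
    signature: Signature,
    targetsA,
    targetsB,
    extra_sets: dict[str, set[str]] | None = None,
) -> Signature:
    """Restrict the signature to genes targeted by BOTH lists.

    Provenance is preserved. ``extra_sets`` adds informational overlap counts
    to the reduction metadata (e.g. how many of the shared-target genes are
    also targets of an RNA-binding protein).
    """
    setA, setB = set(targetsA), set(targetsB)
    if not signature.genes or not setA or not setB:
        raise ValueError("signature and both target lists must be non-empty")
    kept = [g for g in signature.genes if g in setA and g in setB]
    reduction: dict[str, object] = {
        "from_size": len(signature.genes),
        "shared_target_size": len(kept),
    }
    if extra_sets:
        for name, members in extra_sets.items():
            reduction[f"overlap_{name}"] = len(set(kept) & set(members))
    if not kept:
        log.warning("shared-target reduction produced an empty signature")
    return Signature(kept, {g: signature.provenance[g] for g in kept}, reduction)


# ---------------------------------------------------------------------------


def _root_bipartition(tree: LinkageTree) -> tuple[list[int], list[int]]:
    """Leaf index sets of the two children of the dendrogram root."""
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for idx, (a, b, *_rest) in enumerate(tree.Z):
        members[n + idx] = members[int(a)] + members[int(b)]
    left, right = int(tree.Z[-1, 0]), int(tree.Z[-1, 1])
    return members[left], members[right]


def project_signature(
    external_matrix: ExpressionMatrix,
    signature: Signature,
    exclude_samples=(),
) -> BranchClassification:
    """Cluster an external cohort on the signature genes and split at the root.

    The cohort is subset to matched signature genes (exact symbol equality
    after trimming), gene-median-centered, and its samples clustered by
    average linkage on the uncentered-Pearson distance. LB/RB are the two
    children of the root, LB being the branch containing the first retained
    sample. Errors out when fewer than 20% (or fewer than 10) of the
    signature genes match — usually a sign that identifiers need harmonizing.
    """
    exclude = set(exclude_samples)
    retained = [s for s in external_matrix.sample_ids if s not in exclude]
    if len(retained) < 4:
        raise ValueError("projection needs at least 4 retained samples")
    gene_index = {g.strip(): g for g in external_matrix.gene_ids}
    matched = [gene_index[g.strip()] for g in signature.genes if g.strip() in gene_index]
    match_rate = 100.0 * len(matched) / len(signature.genes)
    if match_rate < 20.0 or len(matched) < 10:
        raise ValueError(
            f"only {len(matched)}/{len(signature.genes)} signature genes "
            f"({match_rate:.1f}%) match the cohort; harmonize gene identifiers"
        )
    sub = external_matrix.subset_samples(retained).subset_genes(matched)
    centered = log2_and_center(sub, log=False, center="median")
    tree = average_linkage(centered, axis="samples")
    left_idx, right_idx = _root_bipartition(tree)
    left = {tree.leaf_ids[i] for i in left_idx}
    lb, rb = (left, set(tree.leaf_ids) - left)
    if retained[0] not in lb:
        lb, rb = rb, lb
    labels = pd.Series("excluded", index=external_matrix.sample_ids, name="branch")
    labels[list(lb)] = "LB"
    labels[list(rb)] = "RB"
    log.info(
        "projection: %d/%d signature genes matched (%.1f%%); LB=%d RB=%d excluded=%d",
        len(matched), len(signature.genes), match_rate, len(lb), len(rb), len(exclude),
    )
    return BranchClassification(labels, matched, match_rate, tree)


def branch_differential(
    external_matrix: ExpressionMatrix,
    classification: BranchClassification,
    fdr_threshold: float = 0.01,
) -> tuple[set[str], set[str], DifferentialTable]:
    """Transcriptome-wide moderated-t statistics between LB and RB.

    Runs on ALL genes of the cohort (not only signature genes), dropping
    excluded samples, and selects at the given FDR with no fold-change filter.
    Returns (up-in-LB, down-in-LB, full table).
    """
    lb = classification.branch("LB")
    rb = classification.branch("RB")
    if len(lb) < 2 or len(rb) < 2:
        raise ValueError("both branches need at least 2 samples")
    keep = lb + rb
    sub = external_matrix.subset_samples(keep)
    groups = pd.Series(
        ["LB" if s in set(lb) else "RB" for s in keep], index=keep, name="branch"
    )
    sub = ExpressionMatrix(sub.values, groups)
    table = moderated_t_table(sub, "LB", "RB")
    up, down = select_differential(table, fdr_threshold=fdr_threshold, fold_threshold=1.0)
    return up, down, table
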