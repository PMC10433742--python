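import numpy as np
import pandas as pd
import pytest

from mirsig import synthetic
from mirsig.clustering import GeneCluster
from mirsig.matrix import ExpressionMatrix
from mirsig.signature import (
    Signature,
    branch_differential,
    build_signature,
    project_signature,
    reduce_shared_targets,
)


class TestBuildSignature:
    def test_union_with_provenance(self):
        sig = build_signature(
            [GeneCluster(1, ["a", "b"]), GeneCluster(2, ["c"])]
        )
        assert sig.genes == ["a", "b", "c"]
        assert sig.provenance["c"] == 2

    def test_duplicate_across_clusters_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            build_signature([GeneCluster(1, ["a"]), GeneCluster(2, ["a"])])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_signature([])


class TestReduceSharedTargets:
    def test_identity_when_targets_cover_signature(self):
        sig = Signature(["a", "b"], {"a": 1, "b": 2})
        out = reduce_shared_targets(sig, {"a", "b"}, {"a", "b"})
        assert out.genes == ["a", "b"]
        assert out.provenance == sig.provenance

    def test_disjoint_targets_empty(self):
        sig = Signature(["a", "b"], {"a": 1, "b": 1})
        out = reduce_shared_targets(sig, {"a"}, {"b"})
        assert out.genes == []

    def test_matches_bruteforce_three_way_intersection(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        sig_genes = list(rng.choice(genes, 200, replace=False))
        sig = Signature(sig_genes, {g: 1 + (i % 5) for i, g in enumerate(sig_genes)})
        A = set(rng.choice(genes, 250, replace=False))
        B = set(rng.choice(genes, 250, replace=False))
        out = reduce_shared_targets(sig, A, B)
        assert set(out.genes) == set(sig_genes) & A & B
        assert set(out.genes) <= set(sig.genes)

    def test_symmetric_in_targets(self):
        sig = Signature(list("abcdef"), {g: 1 for g in "abcdef"})
        A, B = set("abcd"), set("cdef")
        assert reduce_shared_targets(sig, A, B).genes == reduce_shared_targets(sig, B, A).genes

    def test_extra_set_overlap_counted(self):
        sig = Signature(["a", "b", "c"], {g: 1 for g in "abc"})
        out = reduce_shared_targets(sig, {"a", "b"}, {"a", "b"}, extra_sets={"hur": {"a"}})
        assert out.reduction["overlap_hur"] == 1
        assert out.reduction["shared_target_size"] == 2


@pytest.fixture(scope="module")
def cohort():
    genes = [f"SIG{i}" for i in range(150)]
    matrix, truth = synthetic.generate_external_cohort(genes, 20, 2.0, seed=4)
    sig = Signature(genes, {g: 1 for g in genes})
    return matrix, truth, sig


class TestProjection:
    def _agreement(self, labels, truth):
        mapped = truth.map({"B1": "LB", "B2": "RB"})
        agree = (labels == mapped).mean()
        return max(agree, 1 - agree)

    def test_branches_recover_truth(self, cohort):
        matrix, truth, sig = cohort
        classification = project_signature(matrix, sig)
        assert self._agreement(classification.labels, truth) >= 0.95
        assert classification.match_rate == 100.0

    def test_invariant_to_sample_and_gene_order(self, cohort):
        matrix, truth, sig = cohort
        base = project_signature(matrix, sig).labels
        rng = np.random.default_rng(1)
        perm = ExpressionMatrix(
            matrix.values.loc[
                rng.permutation(matrix.gene_ids), rng.permutation(matrix.sample_ids)
            ]
        )
        permuted = project_signature(perm, sig).labels.loc[base.index]
        agree = (permuted == base).mean()
        assert max(agree, 1 - agree) == 1.0  # identical up to branch naming

    def test_invariant_to_positive_sample_rescaling(self, cohort):
        matrix, truth, sig = cohort
        base = project_signature(matrix, sig).labels
        scaled_values = matrix.values.copy()
        scaled_values.iloc[:, 3] *= 2.5
        scaled = project_signature(ExpressionMatrix(scaled_values), sig).labels
        agree = (scaled == base).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_excluded_samples_labelled(self, cohort):
        matrix, truth, sig = cohort
        excluded = matrix.sample_ids[:2]
        classification = project_signature(matrix, sig, exclude_samples=excluded)
        assert (classification.labels[excluded] == "excluded").all()

    def test_low_match_rate_errors(self, cohort):
        matrix, _, _ = cohort
        bad = Signature(
            [f"NOPE{i}" for i in range(100)], {f"NOPE{i}": 1 for i in range(100)}
        )
        with pytest.raises(ValueError, match="harmonize"):
            project_signature(matrix, bad)


class TestBranchDifferential:
    def test_planted_cohort_yields_signature_genes(self):
        genes = [f"SIG{i}" for i in range(100)]
        matrix, truth = synthetic.generate_external_cohort(
            genes, 10, 2.0, n_extra_genes=900, seed=5
        )
        sig = Signature(genes, {g: 1 for g in genes})
        classification = project_signature(matrix, sig)
        up, down, table = branch_differential(matrix, classification, 0.01)
        called = up | down
        # most planted signature genes are recovered, few background genes
        assert len(called & set(genes)) >= 80
        bg_rate = len(called - set(genes)) / 900
        assert bg_rate <= 0.02

    def test_null_cohort_nearly_empty(self):
        """Two arbitrary branches of pure-noise data: ~0 genes at FDR 0.01."""
        rates = []
        for seed in range(5):
            genes = [f"SIG{i}" for i in range(50)]
            matrix, _ = synthetic.generate_external_cohort(
                genes, 10, 0.0, n_extra_genes=1950, seed=seed
            )
            sig = Signature(genes, {g: 1 for g in genes})
            classification = project_signature(matrix, sig)
            up, down, _ = branch_differential(matrix, classification, 0.01)
            rates.append((len(up) + len(down)) / matrix.n_genes)
        assert np.mean(rates) <= 0.01

    def test_identical_branches_zero_genes(self):
        rng = np.random.default_rng(7)
        half = rng.normal(8, 1, size=(200, 4))
        values = pd.DataFrame(
            np.hstack([half, half]),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)],
        )
        matrix = ExpressionMatrix(values)
        labels = pd.Series(
            ["LB"] * 4 + ["RB"] * 4, index=matrix.sample_ids, name="branch"
        )
        from mirsig.signature import BranchClassification

        classification = BranchClassification(labels, matrix.gene_ids[:10], 100.0, None)
        up, down, _ = branch_differential(matrix, classification, 0.01)
        assert up == set() and down == set()

    def test_tiny_branch_rejected(self):
        genes = [f"SIG{i}" for i in range(30)]
        matrix, _ = synthetic.generate_external_cohort(genes, 3, 2.0, seed=8)
        labels = pd.Series("LB", index=matrix.sample_ids, name="branch")
        labels.iloc[0] = "RB"
        from mirsig.signature import BranchClassification

        classification = BranchClassification(labels, genes, 100.0, None)
        with pytest.raises(ValueError, match="2 samples"):
            branch_differential(matrix, classification)
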