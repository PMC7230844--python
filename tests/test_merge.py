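"""Weight bookkeeping, peer consensus, cross-layer merging and reselection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrbank.core import Fingerprint, Layer, LocusGenotype, make_genotype
from ssrbank.compare import gca
from ssrbank.merge import (
    AuditRecord,
    DnaNode,
    ExperimenterNode,
    MergeFlag,
    MergeTree,
    SampleNode,
    assign_weights,
    audit_to_frame,
    cross_layer_merge,
    manual_reselect,
    peer_merge,
)
from conftest import fp


def make_tree(i, j, k, m, leaf_genotypes):
    """Uniform tree with identical leaves built from a genotype dict."""
    samples = []
    for s in range(m):
        expers = []
        for e in range(k):
            dnas = []
            for d in range(j):
                leaves = [
                    fp(f"S{s}E{e}D{d}X{x}", leaf_genotypes) for x in range(i)
                ]
                dnas.append(DnaNode(f"S{s}E{e}D{d}", leaves))
            expers.append(ExperimenterNode(f"S{s}E{e}", dnas))
        samples.append(SampleNode(f"S{s}", expers))
    return MergeTree("V", samples)


BASE = {"L1": (100, 102), "L2": (150, 150), "L3": (200, 204)}


class TestWeights:
    @pytest.mark.parametrize("i,j,k,m,leaf_w", [
        (2, 1, 2, 1, 0.25),
        (1, 1, 1, 1, 1.0),
        (3, 2, 1, 1, 1 / 6),
    ])
    def test_leaf_weights(self, i, j, k, m, leaf_w):
        tree = assign_weights(make_tree(i, j, k, m, BASE))
        leaves = tree.leaves()
        assert len(leaves) == i * j * k * m
        assert all(abs(l.weight - leaf_w) < 1e-12 for l in leaves)
        assert abs(sum(l.weight for l in leaves) - 1.0) < 1e-9

    def test_node_weight_conservation(self):
        # weights of leaves under any node sum to that node's weight
        rng = np.random.default_rng(42)
        for _ in range(5):
            i, j, k, m = (int(rng.integers(1, c + 1)) for c in (4, 3, 3, 2))
            tree = assign_weights(make_tree(i, j, k, m, BASE))
            total = 0.0
            for sample in tree.samples:
                s_sum = 0.0
                for exper in sample.experimenters:
                    e_sum = 0.0
                    for dna in exper.dnas:
                        d_sum = sum(l.weight for l in dna.experiments)
                        assert abs(d_sum - dna.weight) < 1e-9
                        e_sum += d_sum
                    assert abs(e_sum - exper.weight) < 1e-9
                    s_sum += e_sum
                assert abs(s_sum - sample.weight) < 1e-9
                total += s_sum
            assert abs(total - 1.0) < 1e-9

    def test_empty_branch_rejected(self):
        tree = make_tree(1, 1, 1, 1, BASE)
        tree.samples[0].experimenters[0].dnas[0].experiments = []
        with pytest.raises(ValueError):
            assign_weights(tree)


class TestPeerMerge:
    def test_unanimous_locus_retained(self):
        out = peer_merge([fp(f"r{t}", BASE) for t in range(3)])
        assert out.merged.genotypes["L1"].alleles == (100.0, 102.0)
        assert out.support["L1"] == 1.0
        assert out.flags["L1"] is MergeFlag.OK

    def test_two_thirds_majority_wins(self):
        fps = [fp("r0", BASE), fp("r1", BASE),
               fp("r2", {**BASE, "L1": (180, 180)})]
        # 180 outside marker grid sense but fine for merge logic
        out = peer_merge(fps)
        assert out.merged.genotypes["L1"].alleles == (100.0, 102.0)
        assert abs(out.support["L1"] - 2 / 3) < 1e-9
        assert out.flags["L1"] is MergeFlag.OK

    def test_three_of_five_is_flagged(self):
        # 40% noise: support 0.6 does NOT strictly exceed the threshold
        fps = [fp(f"r{t}", BASE) for t in range(3)] + [
            fp("n0", {**BASE, "L1": (120, 124)}),
            fp("n1", {**BASE, "L1": (130, 136)}),
        ]
        out = peer_merge(fps)
        assert out.flags["L1"] is MergeFlag.AUDIT_REQUIRED
        assert out.merged.genotypes["L1"].is_missing
        assert abs(out.support["L1"] - 0.6) < 1e-9
        # untouched loci unaffected
        assert out.flags["L2"] is MergeFlag.OK

    def test_tie_is_flagged(self):
        fps = [fp("r0", BASE), fp("r1", {**BASE, "L1": (120, 124)})]
        out = peer_merge(fps)
        assert out.flags["L1"] is MergeFlag.AUDIT_REQUIRED
        assert len(out.candidates["L1"].genotypes) == 2

    def test_all_missing_drops_locus(self):
        fps = [fp("r0", {**BASE, "L1": None}), fp("r1", {**BASE, "L1": None})]
        out = peer_merge(fps)
        assert out.flags["L1"] is MergeFlag.DROPPED_TO_MISSING
        assert out.merged.genotypes["L1"].is_missing

    def test_missing_counts_in_denominator(self):
        # 2 calls agree but 3 of 5 replicates dropped out: support 0.4
        fps = [fp("r0", BASE), fp("r1", BASE)] + [
            fp(f"d{t}", {**BASE, "L1": None}) for t in range(3)
        ]
        out = peer_merge(fps)
        assert abs(out.support["L1"] - 0.4) < 1e-9
        assert out.flags["L1"] is MergeFlag.AUDIT_REQUIRED

    def test_offset_tolerant_clustering(self):
        # replicates shifted by 1 bp cluster together and keep the modal call
        fps = [
            fp("r0", {"L1": (100, 102)}),
            fp("r1", {"L1": (101, 103)}),
            fp("r2", {"L1": (100, 102)}),
        ]
        out = peer_merge(fps, offset=2.0)
        assert out.merged.genotypes["L1"].alleles == (100.0, 102.0)
        assert out.support["L1"] == 1.0

    def test_single_fingerprint_identity(self):
        src = fp("solo", BASE)
        out = peer_merge([src])
        assert dict(out.merged.genotypes) == dict(src.genotypes)
        assert not out.flagged()

    def test_unequal_weights_rejected(self):
        with pytest.raises(ValueError, match="equal weights"):
            peer_merge([fp("a", BASE, weight=0.5), fp("b", BASE, weight=0.25)])

    def test_mixed_panels_rejected(self):
        with pytest.raises(ValueError):
            peer_merge([fp("a", BASE), fp("b", {"L1": (100, 102)})])

    @given(seed=st.integers(0, 200))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_permutation_invariance_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        choices = [(100, 102), (120, 124), (140, 148)]
        fps = [
            fp(f"r{t}", {"L1": choices[rng.integers(3)], "L2": (150, 150)})
            for t in range(5)
        ]
        base = peer_merge(fps)
        # only assert when a strict majority exists (no tie ambiguity)
        if base.flags["L1"] is MergeFlag.OK:
            for perm in itertools.permutations(fps):
                out = peer_merge(list(perm))
                assert out.merged.genotypes["L1"] == base.merged.genotypes["L1"]


class TestManualReselect:
    def flagged_outcome(self):
        fps = [fp("r0", BASE), fp("r1", {**BASE, "L1": (120, 124)})]
        return peer_merge(fps)

    def test_resolve_tie_to_candidate(self):
        out = self.flagged_outcome()
        pick = out.candidates["L1"].genotypes[0]
        fixed = manual_reselect(out, "L1", pick)
        assert fixed.flags["L1"] is MergeFlag.OK
        assert fixed.notes["L1"] == "manual"
        assert fixed.merged.genotypes["L1"] == pick

    def test_reselect_unflagged_needs_force(self):
        out = self.flagged_outcome()
        with pytest.raises(ValueError, match="force"):
            manual_reselect(out, "L2", make_genotype("L2", [150, 150]))

    def test_unobserved_genotype_needs_force(self):
        out = self.flagged_outcome()
        alien = make_genotype("L1", [300, 302])
        with pytest.raises(ValueError, match="force"):
            manual_reselect(out, "L1", alien)
        fixed = manual_reselect(out, "L1", alien, force=True)
        assert fixed.notes["L1"] == "override"


class TestCrossLayer:
    def test_identical_leaves_reach_variety_unchanged(self):
        tree = make_tree(3, 2, 2, 2, BASE)
        result = cross_layer_merge(tree)
        assert result.fingerprint.layer is Layer.VARIETY
        assert dict(result.fingerprint.genotypes) == dict(fp("x", BASE).genotypes)
        assert result.audit == []
        assert len(result.fingerprint.provenance) == 3 * 2 * 2 * 2

    def test_single_path_tree_is_identity(self):
        tree = make_tree(1, 1, 1, 1, BASE)
        result = cross_layer_merge(tree)
        assert dict(result.fingerprint.genotypes) == dict(fp("x", BASE).genotypes)

    def test_one_noise_leaf_in_three_is_absorbed(self):
        # 33% noise per DNA: consensus recovers, effective loci unchanged
        tree = make_tree(3, 1, 1, 1, BASE)
        noisy = {"L1": (120, 124), "L2": (170, 172), "L3": (230, 238)}
        tree.samples[0].experimenters[0].dnas[0].experiments[2] = fp("noise", noisy)
        result = cross_layer_merge(tree)
        assert dict(result.fingerprint.genotypes) == dict(fp("x", BASE).genotypes)
        assert result.fingerprint.effective_count() == 3
        assert result.audit == []

    def test_audit_traces_layer_of_origin(self):
        tree = make_tree(2, 1, 1, 1, BASE)
        noisy = {"L1": (120, 124), "L2": (150, 150), "L3": (200, 204)}
        tree.samples[0].experimenters[0].dnas[0].experiments[1] = fp("noise", noisy)
        result = cross_layer_merge(tree)
        flags_l1 = [r for r in result.audit if r.marker_id == "L1"]
        assert flags_l1 and flags_l1[0].layer is Layer.EXPERIMENT
        # final outcome surfaces the unresolved locus for reselection
        assert result.final_outcome.flags["L1"] is MergeFlag.AUDIT_REQUIRED
        assert result.final_outcome.candidates["L1"].genotypes

    def test_audit_frame_columns(self):
        tree = make_tree(2, 1, 1, 1, BASE)
        tree.samples[0].experimenters[0].dnas[0].experiments[1] = fp(
            "noise", {**BASE, "L1": (120, 124)})
        frame = audit_to_frame(cross_layer_merge(tree).audit)
        assert list(frame.columns) == [
            "marker_id", "layer", "node_id", "flag", "support", "candidates"
        ]


class TestNoiseRecovery:
    """Consensus behavior at the noise boundary for odd replicate counts."""

    @pytest.mark.parametrize("r,n_noise", [(3, 1), (5, 1), (7, 2)])
    def test_below_40pct_noise_recovers_truth(self, r, n_noise):
        assert n_noise / r < 0.4
        tree = make_tree(r, 1, 1, 1, BASE)
        noisy = {"L1": (120, 124), "L2": (170, 172), "L3": (230, 238)}
        for t in range(n_noise):
            tree.samples[0].experimenters[0].dnas[0].experiments[t] = fp(f"n{t}", noisy)
        result = cross_layer_merge(tree)
        assert dict(result.fingerprint.genotypes) == dict(fp("x", BASE).genotypes)
        assert not result.final_outcome.flagged()

    @pytest.mark.parametrize("r,n_noise", [(5, 2), (7, 3)])
    def test_at_or_above_40pct_noise_flags(self, r, n_noise):
        assert n_noise / r >= 0.4
        tree = make_tree(r, 1, 1, 1, BASE)
        noisy = {"L1": (120, 124), "L2": (170, 172), "L3": (230, 238)}
        for t in range(n_noise):
            tree.samples[0].experimenters[0].dnas[0].experiments[t] = fp(f"n{t}", noisy)
        result = cross_layer_merge(tree)
        assert result.final_outcome.flagged()

    def test_one_bp_perturbed_replicates_recover_truth(self):
        rng = np.random.default_rng(7)
        tree = make_tree(3, 1, 1, 1, BASE)
        truth = fp("t", BASE)
        perturbed = []
        for t in range(3):
            geno = {}
            for m, g in truth.genotypes.items():
                a, b = g.alleles
                geno[m] = (a + rng.choice([-1, 1]), b + rng.choice([-1, 1]))
            perturbed.append(fp(f"p{t}", geno))
        tree.samples[0].experimenters[0].dnas[0].experiments = perturbed
        result = cross_layer_merge(tree, offset=2.0)
        assert not result.final_outcome.flagged()
        for m, g in result.fingerprint.genotypes.items():
            assert gca(g, truth.genotypes[m], 2.0) == 0
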