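"""Hierarchical weighted fingerprint merging.

Replicate fingerprints are consolidated bottom-up along the hierarchy
experiment -> DNA -> experimenter -> sample -> variety. Each experiment
leaf under a branch with counts (i, j, k, m) carries weight 1/(i*j*k*m);
merged fingerprints at the DNA, experimenter and sample layers carry
1/(j*k*m), 1/(k*m) and 1/m, so weights are conserved at every node and sum
to one over the tree.

Peer merging consolidates fingerprints within one layer locus by locus:
genotypes are clustered by offset-tolerant equality, the heaviest cluster
wins, and its modal genotype is retained. A locus whose winning cluster
does not clearly dominate — support not strictly above the effective-data
threshold (default 60%, the complement of a 40% noise boundary) — is
flagged for manual audit and dropped to missing pending reselection. This
is what makes an odd replicate set with strictly less than 40% noise merge
cleanly while 40% or more degrades the effective-locus count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core import Fingerprint, Layer, LocusGenotype, check_shared_panel
from .compare import gca

#: Winning-cluster support must strictly exceed this fraction for a merged
#: locus to count as effective data (complement of the 40% noise boundary).
EFFECTIVE_SUPPORT_THRESHOLD = 0.6


class MergeFlag(str, Enum):
    OK = "OK"
    AUDIT_REQUIRED = "AUDIT_REQUIRED"
    DROPPED_TO_MISSING = "DROPPED_TO_MISSING"


# ---------------------------------------------------------------------------
# merge tree


@dataclass
class DnaNode:
    """One DNA solution with its i experiment-layer replicate fingerprints."""

    dna_id: str
    experiments: list[Fingerprint]
    weight: float = 0.0


@dataclass
class ExperimenterNode:
    experimenter_id: str
    dnas: list[DnaNode]
    weight: float = 0.0


@dataclass
class SampleNode:
    sample_id: str
    experimenters: list[ExperimenterNode]
    weight: float = 0.0


@dataclass
class MergeTree:
    """The experiment/DNA/experimenter/sample hierarchy under one variety.

    Branch counts (i, j, k, m) may differ between branches; weights are
    always computed from the counts local to each branch.
    """

    variety_id: str
    samples: list[SampleNode]

    def leaves(self) -> list[Fingerprint]:
        return [
            fp
            for s in self.samples
            for e in s.experimenters
            for d in e.dnas
            for fp in d.experiments
        ]


def assign_weights(tree: MergeTree) -> MergeTree:
    """Set leaf and internal-node weights by the 1/(i*j*k*m) scheme.

    Mutates and returns the tree; leaf fingerprints are replaced with
    weight-bearing copies. Total weight over the tree is exactly 1.
    """
    m = len(tree.samples)
    if m == 0:
        raise ValueError("merge tree has no samples")
    for sample in tree.samples:
        k = len(sample.experimenters)
        if k == 0:
            raise ValueError(f"sample {sample.sample_id} has no experimenters")
        sample.weight = 1.0 / m
        for exper in sample.experimenters:
            j = len(exper.dnas)
            if j == 0:
                raise ValueError(f"experimenter {exper.experimenter_id} has no DNA")
            exper.weight = 1.0 / (k * m)
            for dna in exper.dnas:
                i = len(dna.experiments)
                if i == 0:
                    raise ValueError(f"DNA {dna.dna_id} has no experiments")
                dna.weight = 1.0 / (j * k * m)
                w = 1.0 / (i * j * k * m)
                dna.experiments = [fp.with_weight(w) for fp in dna.experiments]
    return tree


# ---------------------------------------------------------------------------
# peer (same-layer) merging


@dataclass(frozen=True)
class LocusCandidates:
    """Cluster representatives observed at one locus, with their support."""

    genotypes: tuple[LocusGenotype, ...]
    supports: tuple[float, ...]


@dataclass
class MergeOutcome:
    """Result of one peer merge: the merged fingerprint plus audit state."""

    merged: Fingerprint
    support: dict[str, float]
    flags: dict[str, MergeFlag]
    candidates: dict[str, LocusCandidates]
    notes: dict[str, str] = field(default_factory=dict)

    def flagged(self) -> list[str]:
        return [m for m, f in self.flags.items() if f is MergeFlag.AUDIT_REQUIRED]


def _merge_locus(
    calls: Sequence[tuple[LocusGenotype, float]],
    offset: float,
    threshold: float,
) -> tuple[LocusGenotype | None, float, MergeFlag, LocusCandidates]:
    """Consensus at one locus. ``calls`` pairs each genotype with its weight."""
    marker = calls[0][0].marker_id
    total_w = sum(w for _, w in calls)
    effective = [(g, w) for g, w in calls if not g.is_missing]
    if not effective:
        return None, 0.0, MergeFlag.DROPPED_TO_MISSING, LocusCandidates((), ())

    # greedy clustering by offset-tolerant equality, in input order; a call
    # joins the first cluster whose representative it matches
    clusters: list[dict] = []
    for g, w in effective:
        for c in clusters:
            if gca(g, c["rep"], offset) == 0:
                c["members"].append((g, w))
                c["weight"] += w
                break
        else:
            clusters.append({"rep": g, "members": [(g, w)], "weight": w})

    best = max(clusters, key=lambda c: c["weight"])
    tied = sum(1 for c in clusters if abs(c["weight"] - best["weight"]) < 1e-12) > 1

    def representative(cluster: dict) -> LocusGenotype:
        # exact modal genotype within the cluster; ties broken by the
        # smallest allele pair
        tallies: dict[LocusGenotype, float] = {}
        for g, w in cluster["members"]:
            tallies[g] = tallies.get(g, 0.0) + w
        top = max(tallies.values())
        modal = [g for g, w in tallies.items() if abs(w - top) < 1e-12]
        return min(modal, key=lambda g: (g.allele_low, g.allele_high))

    cands = sorted(clusters, key=lambda c: -c["weight"])
    candidates = LocusCandidates(
        tuple(representative(c) for c in cands),
        tuple(c["weight"] / total_w for c in cands),
    )
    support = best["weight"] / total_w
    # support must strictly exceed the threshold; the 1e-9 guard keeps
    # weight-sum rounding (e.g. 3 * (1/5) = 0.6000000000000001) from
    # tipping an exact-boundary locus over the line
    if tied or support <= threshold + 1e-9:
        # no clear winner: park the locus as missing pending manual audit
        return None, support, MergeFlag.AUDIT_REQUIRED, candidates
    return representative(best), support, MergeFlag.OK, candidates


def peer_merge(
    fps: Sequence[Fingerprint],
    offset: float = 2.0,
    effective_threshold: float = EFFECTIVE_SUPPORT_THRESHOLD,
    merged_id: str | None = None,
    layer: Layer | None = None,
) -> MergeOutcome:
    """Merge replicate fingerprints of one layer, locus by locus.

    Missing calls do not vote but still count in the support denominator,
    so heavy dropout at a locus forces an audit rather than silently
    promoting a minority call. Input weights must be equal within the layer
    (the weight scheme guarantees this for siblings).
    """
    if not fps:
        raise ValueError("peer_merge needs at least one fingerprint")
    markers = check_shared_panel(fps)
    w0 = fps[0].weight
    if any(abs(fp.weight - w0) > 1e-12 for fp in fps):
        raise ValueError("peer_merge requires equal weights within the layer")

    merged_id = merged_id or "+".join(fp.entity_id for fp in fps)
    layer = layer or fps[0].layer
    genotypes: dict[str, LocusGenotype] = {}
    support: dict[str, float] = {}
    flags: dict[str, MergeFlag] = {}
    candidates: dict[str, LocusCandidates] = {}
    for marker in markers:
        calls = [(fp.genotypes[marker], fp.weight) for fp in fps]
        g, s, flag, cand = _merge_locus(calls, offset, effective_threshold)
        genotypes[marker] = g if g is not None else LocusGenotype(marker)
        support[marker] = s
        flags[marker] = flag
        candidates[marker] = cand

    provenance: tuple[str, ...] = ()
    for fp in fps:
        provenance += fp.provenance
    merged = Fingerprint(
        entity_id=merged_id,
        layer=layer,
        genotypes=genotypes,
        weight=min(1.0, sum(fp.weight for fp in fps)),
        provenance=provenance,
        name=fps[0].name,
        synonyms=fps[0].synonyms,
    )
    return MergeOutcome(merged, support, flags, candidates)


def manual_reselect(
    outcome: MergeOutcome,
    marker_id: str,
    genotype: LocusGenotype,
    force: bool = False,
) -> MergeOutcome:
    """Resolve an audited locus by hand.

    The chosen genotype must be one of the observed cluster representatives
    at that locus; an unobserved genotype, or reselection of an unflagged
    locus, requires ``force`` and is recorded as an override.
    """
    flag = outcome.flags.get(marker_id)
    if flag is None:
        raise KeyError(f"unknown marker {marker_id}")
    if flag is not MergeFlag.AUDIT_REQUIRED and not force:
        raise ValueError(
            f"{marker_id} is {flag.value}, not AUDIT_REQUIRED; pass force=True to override"
        )
    observed = genotype in outcome.candidates[marker_id].genotypes
    if not observed and not force:
        raise ValueError(
            f"{genotype} was not observed at {marker_id}; pass force=True to override"
        )
    genotypes = dict(outcome.merged.genotypes)
    genotypes[marker_id] = genotype
    merged = replace(outcome.merged, genotypes=genotypes)
    flags = dict(outcome.flags)
    flags[marker_id] = MergeFlag.OK
    notes = dict(outcome.notes)
    notes[marker_id] = "manual" if observed else "override"
    return MergeOutcome(merged, dict(outcome.support), flags, dict(outcome.candidates), notes)


# ---------------------------------------------------------------------------
# cross-layer merging


@dataclass(frozen=True)
class AuditRecord:
    """One non-OK locus flag with the layer and node it arose at."""

    marker_id: str
    layer: Layer
    node_id: str
    flag: MergeFlag
    support: float
    candidates: LocusCandidates


@dataclass
class CrossLayerResult:
    fingerprint: Fingerprint
    audit: list[AuditRecord]
    final_outcome: MergeOutcome


def _collect(outcome: MergeOutcome, layer: Layer, node_id: str) -> list[AuditRecord]:
    return [
        AuditRecord(m, layer, node_id, f, outcome.support[m], outcome.candidates[m])
        for m, f in outcome.flags.items()
        if f is not MergeFlag.OK
    ]


def cross_layer_merge(
    tree: MergeTree,
    offset: float = 2.0,
    effective_threshold: float = EFFECTIVE_SUPPORT_THRESHOLD,
) -> CrossLayerResult:
    """Merge a weighted tree bottom-up to the variety fingerprint.

    Peer merging is applied at the experiment, DNA, experimenter and sample
    layers in turn. The audit report aggregates every non-OK locus flag
    with its layer of origin so a data error can be traced to the stage
    (instrument run, extraction, analyst, batch) that produced it. A locus
    still unresolved in the final merge surfaces as AUDIT_REQUIRED on the
    returned outcome, carrying the candidates of the stage where the
    conflict arose, so manual reselection can be applied to the end result.
    """
    assign_weights(tree)
    audit: list[AuditRecord] = []

    sample_fps: list[Fingerprint] = []
    for sample in tree.samples:
        exper_fps: list[Fingerprint] = []
        for exper in sample.experimenters:
            dna_fps: list[Fingerprint] = []
            for dna in exper.dnas:
                out = peer_merge(
                    dna.experiments, offset, effective_threshold,
                    merged_id=dna.dna_id, layer=Layer.DNA,
                )
                audit += _collect(out, Layer.EXPERIMENT, dna.dna_id)
                dna_fps.append(out.merged.with_weight(dna.weight))
            out = peer_merge(
                dna_fps, offset, effective_threshold,
                merged_id=exper.experimenter_id, layer=Layer.EXPERIMENTER,
            )
            audit += _collect(out, Layer.DNA, exper.experimenter_id)
            exper_fps.append(out.merged.with_weight(exper.weight))
        out = peer_merge(
            exper_fps, offset, effective_threshold,
            merged_id=sample.sample_id, layer=Layer.SAMPLE,
        )
        audit += _collect(out, Layer.EXPERIMENTER, sample.sample_id)
        sample_fps.append(out.merged.with_weight(sample.weight))

    final = peer_merge(
        sample_fps, offset, effective_threshold,
        merged_id=tree.variety_id, layer=Layer.VARIETY,
    )
    audit += _collect(final, Layer.SAMPLE, tree.variety_id)

    # surface unresolved lower-layer conflicts on the final outcome so that
    # manual_reselect has candidates to offer
    for rec in audit:
        marker = rec.marker_id
        if final.merged.genotypes[marker].is_missing and final.flags[
            marker
        ] is not MergeFlag.AUDIT_REQUIRED:
            final.flags[marker] = MergeFlag.AUDIT_REQUIRED
            if not final.candidates[marker].genotypes:
                final.candidates[marker] = rec.candidates
    return CrossLayerResult(final.merged, audit, final)


def audit_to_frame(audit: Sequence[AuditRecord]) -> pd.DataFrame:
    """Audit report as a table (one row per flagged locus occurrence)."""
    rows = [
        {
            "marker_id": r.marker_id,
            "layer": r.layer.value,
            "node_id": r.node_id,
            "flag": r.flag.value,
            "support": r.support,
            "candidates": ";".join(
                f"[{g.allele_low},{g.allele_high}]" for g in r.candidates.genotypes
            ),
        }
        for r in audit
    ]
    return pd.DataFrame(
        rows, columns=["marker_id", "layer", "node_id", "flag", "support", "candidates"]
    )
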