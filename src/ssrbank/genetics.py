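"""Genetic analysis over fingerprint sets.

Allele ("gene") frequency tables, pairwise genetic distance matrices under
a registry of twelve standard methods, and UPGMA / neighbour-joining
cluster trees emitted as newick.

Allele identity for the frequency- and sharing-based methods uses exact
size equality, optionally after snapping observed sizes to each marker's
repeat-unit grid (recommended for raw CE reads, whose 1-2 bp error would
otherwise split one allele into several). The comparison-derived methods
(simple matching, difference count, difference ratio) instead reuse the
offset-tolerant locus comparator.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDistanceMatrix

from .core import ComparisonParams, Fingerprint, MarkerDef, check_shared_panel
from .compare import compare_pair, gca


@dataclass
class AlleleFrequencyTable:
    """Per-marker allele frequencies over a fingerprint set.

    The allele-count basis at each marker is twice the number of
    fingerprints effective there; missing loci are excluded from that
    marker's denominator. Frequencies at a marker sum to one whenever any
    allele was observed.
    """

    frequencies: dict[str, dict[float, float]]
    counts: dict[str, int]
    n_fingerprints: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_id": m, "allele": a, "frequency": f, "allele_count": self.counts[m]}
            for m, row in self.frequencies.items()
            for a, f in sorted(row.items())
        ]
        return pd.DataFrame(rows, columns=["marker_id", "allele", "frequency", "allele_count"])


def _snap(size: float, marker: MarkerDef | None) -> float:
    return marker.snap_to_grid(size) if marker is not None else size


def allele_frequencies(
    fps: Sequence[Fingerprint],
    panel: Sequence[MarkerDef] | None = None,
    snap_to_grid: bool = True,
) -> AlleleFrequencyTable:
    """Tally both alleles of every effective genotype, per marker."""
    if not fps:
        raise ValueError("allele_frequencies needs at least one fingerprint")
    markers = check_shared_panel(fps)
    by_id = {m.marker_id: m for m in panel} if panel else {}
    freqs: dict[str, dict[float, float]] = {}
    counts: dict[str, int] = {}
    for marker in markers:
        mdef = by_id.get(marker) if snap_to_grid else None
        tally: dict[float, int] = {}
        n = 0
        for fp in fps:
            g = fp.genotypes[marker]
            if g.is_missing:
                continue
            for a in g.alleles:
                a = _snap(a, mdef)
                tally[a] = tally.get(a, 0) + 1
                n += 1
        counts[marker] = n
        freqs[marker] = {a: c / n for a, c in tally.items()} if n else {}
    return AlleleFrequencyTable(freqs, counts, len(fps))


# ---------------------------------------------------------------------------
# distance registry
#
# Frequency-based formulas treat each fingerprint as a one-individual
# population: allele frequencies per locus are 1 (homozygote) or 1/2 each
# (heterozygote). Sums run over loci effective in both fingerprints.


def _locus_freqs(fp: Fingerprint, marker: str, mdef: MarkerDef | None) -> dict[float, float]:
    g = fp.genotypes[marker]
    a, b = (_snap(x, mdef) for x in g.alleles)
    return {a: 1.0} if a == b else {a: 0.5, b: 0.5}


class _PairContext:
    """Shared per-pair scratch: effective loci and their frequency vectors."""

    def __init__(self, f1: Fingerprint, f2: Fingerprint,
                 by_id: Mapping[str, MarkerDef], params: ComparisonParams):
        self.f1, self.f2, self.params = f1, f2, params
        self.loci = [
            m for m in f1.markers
            if not f1.genotypes[m].is_missing and not f2.genotypes[m].is_missing
        ]
        self.by_id = by_id

    def freq_pairs(self):
        for m in self.loci:
            mdef = self.by_id.get(m)
            x = _locus_freqs(self.f1, m, mdef)
            y = _locus_freqs(self.f2, m, mdef)
            yield m, x, y

    def presence_sets(self):
        A, B = set(), set()
        for m in self.loci:
            mdef = self.by_id.get(m)
            A |= {(m, _snap(a, mdef)) for a in self.f1.genotypes[m].alleles}
            B |= {(m, _snap(a, mdef)) for a in self.f2.genotypes[m].alleles}
        return A, B


def _shared_allele(ctx: _PairContext) -> float:
    # 1 - mean proportion of shared alleles per locus (multiset overlap / 2)
    if not ctx.loci:
        return 0.0
    shared = []
    for m, x, y in ctx.freq_pairs():
        s = sum(min(2 * x.get(a, 0.0), 2 * y.get(a, 0.0)) for a in set(x) | set(y))
        shared.append(s / 2.0)
    return 1.0 - float(np.mean(shared))


def _nei_standard(ctx: _PairContext) -> float:
    jxy = jx = jy = 0.0
    for m, x, y in ctx.freq_pairs():
        alleles = set(x) | set(y)
        jxy += sum(x.get(a, 0.0) * y.get(a, 0.0) for a in alleles)
        jx += sum(v * v for v in x.values())
        jy += sum(v * v for v in y.values())
    if jx == 0 or jy == 0:
        return 0.0
    identity = jxy / math.sqrt(jx * jy)
    if identity <= 0:
        return float("inf")
    return max(0.0, -math.log(identity))


def _nei_da(ctx: _PairContext) -> float:
    if not ctx.loci:
        return 0.0
    total = 0.0
    for m, x, y in ctx.freq_pairs():
        total += sum(math.sqrt(x.get(a, 0.0) * y.get(a, 0.0)) for a in set(x) | set(y))
    return 1.0 - total / len(ctx.loci)


def _rogers(ctx: _PairContext) -> float:
    if not ctx.loci:
        return 0.0
    total = 0.0
    for m, x, y in ctx.freq_pairs():
        ss = sum((x.get(a, 0.0) - y.get(a, 0.0)) ** 2 for a in set(x) | set(y))
        total += math.sqrt(0.5 * ss)
    return total / len(ctx.loci)


def _modified_rogers(ctx: _PairContext) -> float:
    if not ctx.loci:
        return 0.0
    ss = 0.0
    for m, x, y in ctx.freq_pairs():
        ss += sum((x.get(a, 0.0) - y.get(a, 0.0)) ** 2 for a in set(x) | set(y))
    return math.sqrt(ss / (2.0 * len(ctx.loci)))


def _cavalli_sforza(ctx: _PairContext) -> float:
    if not ctx.loci:
        return 0.0
    total = 0.0
    for m, x, y in ctx.freq_pairs():
        fxy = sum(math.sqrt(x.get(a, 0.0) * y.get(a, 0.0)) for a in set(x) | set(y))
        total += (2.0 / math.pi) * math.sqrt(max(0.0, 2.0 * (1.0 - fxy)))
    return total / len(ctx.loci)


def _simple_matching(ctx: _PairContext) -> float:
    # fraction of compared loci that differ under the offset comparator
    if not ctx.loci:
        return 0.0
    n = ctx.params.base_offset_bp
    diff = sum(
        gca(ctx.f1.genotypes[m], ctx.f2.genotypes[m], n) for m in ctx.loci
    )
    return diff / len(ctx.loci)


def _jaccard(ctx: _PairContext) -> float:
    A, B = ctx.presence_sets()
    if not A and not B:
        return 0.0
    return 1.0 - len(A & B) / len(A | B)


def _dice(ctx: _PairContext) -> float:
    A, B = ctx.presence_sets()
    if not A and not B:
        return 0.0
    return 1.0 - 2.0 * len(A & B) / (len(A) + len(B))


def _euclidean(ctx: _PairContext) -> float:
    ss = 0.0
    for m, x, y in ctx.freq_pairs():
        ss += sum((x.get(a, 0.0) - y.get(a, 0.0)) ** 2 for a in set(x) | set(y))
    return math.sqrt(ss)


def _diff_count(ctx: _PairContext) -> float:
    return float(compare_pair(ctx.f1, ctx.f2, ctx.params).D)


def _diff_ratio(ctx: _PairContext) -> float:
    return compare_pair(ctx.f1, ctx.f2, ctx.params).x


DISTANCE_METHODS: dict[str, Callable[[_PairContext], float]] = {
    "shared_allele": _shared_allele,
    "nei_standard": _nei_standard,
    "nei_da": _nei_da,
    "rogers": _rogers,
    "modified_rogers": _modified_rogers,
    "cavalli_sforza": _cavalli_sforza,
    "simple_matching": _simple_matching,
    "jaccard": _jaccard,
    "dice": _dice,
    "euclidean": _euclidean,
    "diff_count": _diff_count,
    "diff_ratio": _diff_ratio,
}


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def genetic_distance(
    fps: Sequence[Fingerprint],
    method: str = "shared_allele",
    panel: Sequence[MarkerDef] | None = None,
    params: ComparisonParams | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix under one of the registry methods."""
    if method not in DISTANCE_METHODS:
        raise KeyError(
            f"unknown distance method {method!r}; available: "
            + ", ".join(sorted(DISTANCE_METHODS))
        )
    if len(fps) < 2:
        raise ValueError("genetic_distance needs at least two fingerprints")
    check_shared_panel(fps)
    params = params or ComparisonParams()
    by_id = {m.marker_id: m for m in panel} if panel else {}
    fn = DISTANCE_METHODS[method]
    n = len(fps)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = fn(_PairContext(fps[a], fps[b], by_id, params))
    return DistanceMatrix(tuple(fp.entity_id for fp in fps), out, method)


# ---------------------------------------------------------------------------
# cluster trees


def build_tree(dm: DistanceMatrix, method: str = "UPGMA") -> str:
    """Cluster a distance matrix into a newick tree (UPGMA or NJ).

    UPGMA trees are ultrametric (equal root-to-leaf path lengths);
    neighbour joining recovers additive topologies. Non-leaf node labels
    are stripped from the output.
    """
    method = method.upper()
    if method not in ("UPGMA", "NJ"):
        raise ValueError(f"tree method must be UPGMA or NJ, got {method!r}")
    names = list(dm.ids)
    lower = [[float(dm.values[a][b]) for b in range(a + 1)] for a in range(len(names))]
    bio_dm = _BioDistanceMatrix(names, lower)
    ctor = DistanceTreeConstructor()
    tree = ctor.upgma(bio_dm) if method == "UPGMA" else ctor.nj(bio_dm)
    for clade in tree.get_nonterminals():
        clade.name = None
    # NJ can produce tiny negative branch lengths on noisy matrices
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.12g")
    return buf.getvalue().strip()


def render_dendrogram(newick: str) -> str:
    """Plain-text render of a newick tree (ASCII dendrogram)."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    buf = io.StringIO()
    Phylo.draw_ascii(tree, file=buf)
    return buf.getvalue()
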