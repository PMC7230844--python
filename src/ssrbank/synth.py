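"""Synthetic SSR genotyping data.

Generates ground-truth variety fingerprints on a dinucleotide marker
panel, then emulates the experimental hierarchy: replicate CE runs with
fractional-bp read error of 1-2 bp, per-locus allele dropout, and whole
noise replicates (a failed or swapped run whose calls are unrelated to the
sample). Every pipeline stage can therefore be exercised end to end
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Fingerprint,
    HierarchyIndex,
    Layer,
    LocusGenotype,
    MarkerDef,
    make_genotype,
)
from .compare import gca
from .merge import DnaNode, ExperimenterNode, MergeTree, SampleNode


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic genotyping campaign.

    Defaults model a routine variety-fingerprinting experiment: a 20-locus
    dinucleotide panel, three repeated CE runs per DNA by one experimenter
    (the canonical three-repeat QC design), moderate heterozygosity, a
    small allele-dropout rate, and a CE sizing error of +/-1 bp (common)
    or +/-2 bp (rare) per allele read — the magnitude that motivates the
    2 bp base offset.
    """

    n_markers: int = 20
    alleles_per_marker: int = 10
    repeat_unit: int = 2
    size_min: float = 100.0
    heterozygosity: float = 0.5
    dropout_rate: float = 0.02
    p_err1_bp: float = 0.05  # per-allele probability of a +/-1 bp read
    p_err2_bp: float = 0.01  # per-allele probability of a +/-2 bp read
    noise_fraction: float = 0.0  # fraction of experiment replicates per DNA
    #: noise calls are kept gca-distinct from truth at this offset; the
    #: default of base offset (2) + max read error (2) means a noise call
    #: can never chain into the truth cluster through an erred clean read
    noise_clearance_bp: float = 4.0
    hierarchy: HierarchyIndex = field(default_factory=HierarchyIndex)
    n_varieties: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.alleles_per_marker < 2:
            raise ValueError("need at least 2 alleles per marker")
        for name in ("heterozygosity", "dropout_rate", "p_err1_bp", "p_err2_bp",
                     "noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_err1_bp + self.p_err2_bp > 1.0:
            raise ValueError("size-error probabilities exceed 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_panel(config: SimConfig) -> list[MarkerDef]:
    """A panel of ``n_markers`` markers on the repeat-unit grid.

    Marker size ranges are staggered so allele sets are marker specific,
    as with a real multiplex panel.
    """
    panel = []
    for t in range(config.n_markers):
        lo = config.size_min + (t % 5) * 10.0
        hi = lo + (config.alleles_per_marker - 1) * config.repeat_unit
        panel.append(
            MarkerDef(f"M{t + 1:02d}", panel_id="P1", repeat_unit=config.repeat_unit,
                      size_min=lo, size_max=hi)
        )
    return panel


def _draw_genotype(marker: MarkerDef, rng: np.random.Generator,
                   heterozygosity: float) -> LocusGenotype:
    # draw truth from the interior of the grid so a +/-2 bp read error can
    # never push an allele outside the marker's declared size range
    grid = marker.allele_grid()
    if len(grid) >= 4:
        grid = grid[1:-1]
    a = grid[rng.integers(len(grid))]
    if rng.random() < heterozygosity:
        b = a
        while b == a:
            b = grid[rng.integers(len(grid))]
    else:
        b = a
    return make_genotype(marker.marker_id, [a, b])


def generate_truth(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[MarkerDef], dict[str, Fingerprint]]:
    """Ground-truth variety fingerprints on a fresh panel.

    All allele sizes lie on the repeat-unit grid; the heterozygosity rate
    holds in expectation per locus.
    """
    rng = config.rng() if rng is None else rng
    panel = make_panel(config)
    truths: dict[str, Fingerprint] = {}
    for v in range(config.n_varieties):
        vid = f"V{v + 1:03d}"
        genotypes = {
            m.marker_id: _draw_genotype(m, rng, config.heterozygosity) for m in panel
        }
        truths[vid] = Fingerprint(vid, Layer.VARIETY, genotypes, name=vid)
    return panel, truths


def perturb_genotype(
    g: LocusGenotype, config: SimConfig, rng: np.random.Generator
) -> LocusGenotype:
    """Apply dropout and per-allele CE read error to one true genotype."""
    if rng.random() < config.dropout_rate:
        return LocusGenotype(g.marker_id)
    out = []
    for a in g.alleles:
        u = rng.random()
        if u < config.p_err2_bp:
            a += 2.0 * (1 if rng.random() < 0.5 else -1)
        elif u < config.p_err2_bp + config.p_err1_bp:
            a += 1.0 * (1 if rng.random() < 0.5 else -1)
        out.append(a)
    return make_genotype(g.marker_id, out)


def noise_genotype(
    marker: MarkerDef,
    truth: LocusGenotype,
    rng: np.random.Generator,
    offset: float = 2.0,
) -> LocusGenotype:
    """A uniform off-truth draw from the marker's allele grid.

    Redrawn until offset-tolerantly distinct from the true genotype, so a
    noise call can never be mistaken for a sized read of the real allele.
    """
    grid = marker.allele_grid()
    for _ in range(1000):
        a, b = grid[rng.integers(len(grid))], grid[rng.integers(len(grid))]
        g = make_genotype(marker.marker_id, [a, b])
        if truth.is_missing or gca(g, truth, offset) == 1:
            return g
    raise RuntimeError(
        f"{marker.marker_id}: allele range too narrow to draw off-truth noise"
    )


def noise_fingerprint(
    panel: list[MarkerDef],
    truth: Fingerprint,
    entity_id: str,
    rng: np.random.Generator,
    offset: float = 2.0,
) -> Fingerprint:
    """A whole noise replicate: every locus an off-truth uniform draw."""
    by_id = {m.marker_id: m for m in panel}
    genotypes = {
        mid: noise_genotype(by_id[mid], g, rng, offset)
        for mid, g in truth.genotypes.items()
    }
    return Fingerprint(entity_id, Layer.EXPERIMENT, genotypes, name=truth.name)


def generate_replicates(
    truth: Fingerprint,
    config: SimConfig,
    panel: list[MarkerDef],
    rng: np.random.Generator | None = None,
    sample_prefix: str | None = None,
) -> MergeTree:
    """Build a replicate tree for one variety with perturbed leaves.

    Per DNA node, ``round(noise_fraction * i)`` of the i experiment
    replicates are replaced by whole noise fingerprints; the remainder are
    the truth with read error and dropout applied.
    """
    rng = config.rng() if rng is None else rng
    h = config.hierarchy
    prefix = sample_prefix or truth.entity_id
    n_noise = int(round(config.noise_fraction * h.i))
    samples = []
    for s in range(h.m):
        sid = f"{prefix}-S{s + 1}"
        expers = []
        for k in range(h.k):
            eid = f"{sid}-E{k + 1}"
            dnas = []
            for j in range(h.j):
                did = f"{eid}-D{j + 1}"
                leaves = []
                for i in range(h.i):
                    xid = f"{did}-X{i + 1}"
                    if i < h.i - n_noise:
                        genotypes = {
                            mid: perturb_genotype(g, config, rng)
                            for mid, g in truth.genotypes.items()
                        }
                        fp = Fingerprint(xid, Layer.EXPERIMENT, genotypes,
                                         name=truth.name)
                    else:
                        fp = noise_fingerprint(
                            panel, truth, xid, rng, config.noise_clearance_bp
                        )
                    leaves.append(fp)
                dnas.append(DnaNode(did, leaves))
            expers.append(ExperimenterNode(eid, dnas))
        samples.append(SampleNode(sid, expers))
    return MergeTree(truth.entity_id, samples)
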