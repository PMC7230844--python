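"""Domain model for diploid SSR (microsatellite) fingerprints.

An SSR fingerprint is a profile of fragment-length genotypes over a fixed
panel of markers. Alleles are named by fragment size in base pairs, as read
from capillary electrophoresis (CE); because many high-polymorphism markers
use 2-bp repeat motifs, CE sizing carries a 1-2 bp read error, which the
comparison and merging machinery absorbs through a configurable base offset.

Everything downstream (comparison, merging, storage, genetics) works in
terms of the types defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Layer(str, Enum):
    """Provenance layer of a fingerprint in the merge hierarchy."""

    EXPERIMENT = "EXPERIMENT"
    DNA = "DNA"
    EXPERIMENTER = "EXPERIMENTER"
    SAMPLE = "SAMPLE"
    VARIETY = "VARIETY"


class GenotypeStatus(str, Enum):
    EFFECTIVE = "EFFECTIVE"
    MISSING = "MISSING"


@dataclass(frozen=True)
class MarkerDef:
    """One SSR marker of a panel.

    Parameters
    ----------
    marker_id : str
        Unique marker name within the panel set.
    panel_id : str
        Multiplex panel this marker belongs to.
    repeat_unit : int
        Repeat motif length in bp (2 for dinucleotide SSRs).
    size_min, size_max : float
        Expected allele size range in bp.
    """

    marker_id: str
    panel_id: str
    repeat_unit: int = 2
    size_min: float = 100.0
    size_max: float = 300.0

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.repeat_unit < 1:
            raise ValueError(f"repeat_unit must be >= 1, got {self.repeat_unit}")
        if not self.size_min < self.size_max:
            raise ValueError(
                f"size_min must be < size_max ({self.size_min} >= {self.size_max})"
            )

    def allele_grid(self) -> tuple[float, ...]:
        """All allele sizes on the repeat-unit grid within the size range."""
        n = int(math.floor((self.size_max - self.size_min) / self.repeat_unit))
        return tuple(round(self.size_min + t * self.repeat_unit, 1) for t in range(n + 1))

    def snap_to_grid(self, size: float) -> float:
        """Round an observed size to the nearest grid allele (bins CE read error)."""
        t = round((size - self.size_min) / self.repeat_unit)
        t = max(0, min(t, int((self.size_max - self.size_min) // self.repeat_unit)))
        return round(self.size_min + t * self.repeat_unit, 1)


@dataclass(frozen=True, order=True)
class LocusGenotype:
    """A diploid allele-size call at one marker, or a missing call.

    Effective genotypes carry both alleles ordered ``allele_low <=
    allele_high``; homozygotes are stored as an equal pair. A missing locus
    carries no alleles at all — a half-called locus is not representable
    (use :func:`make_genotype`, which rejects single calls).
    """

    marker_id: str
    allele_low: float | None = None
    allele_high: float | None = None

    def __post_init__(self) -> None:
        low, high = self.allele_low, self.allele_high
        if (low is None) != (high is None):
            raise ValueError(
                f"{self.marker_id}: diploid genotype needs both alleles or neither"
            )
        if low is not None and high is not None and low > high:
            raise ValueError(f"{self.marker_id}: allele_low > allele_high")

    @property
    def is_missing(self) -> bool:
        return self.allele_low is None

    @property
    def status(self) -> GenotypeStatus:
        return GenotypeStatus.MISSING if self.is_missing else GenotypeStatus.EFFECTIVE

    @property
    def alleles(self) -> tuple[float, float]:
        if self.is_missing:
            raise ValueError(f"{self.marker_id}: missing genotype has no alleles")
        return (self.allele_low, self.allele_high)  # type: ignore[return-value]


def make_genotype(marker_id: str, alleles: Sequence[float] = ()) -> LocusGenotype:
    """Build a :class:`LocusGenotype` from zero or two allele sizes.

    Sizes are rounded to 0.1 bp (CE sizing resolution) and ordered. Zero
    sizes yield a MISSING call. Exactly one size is rejected: under the
    diploid contract a half-called locus is not a genotype (importers may
    duplicate a single call to a homozygote explicitly, not here).
    """
    if len(alleles) == 1:
        raise ValueError(
            f"{marker_id}: exactly one allele supplied; diploid calls need two "
            "(or zero for a missing locus)"
        )
    if len(alleles) > 2:
        raise ValueError(f"{marker_id}: more than two alleles (polyploids unsupported)")
    if not alleles:
        return LocusGenotype(marker_id)
    a, b = (round(float(s), 1) for s in alleles)
    if a <= 0 or b <= 0:
        raise ValueError(f"{marker_id}: allele sizes must be positive")
    low, high = (a, b) if a <= b else (b, a)
    return LocusGenotype(marker_id, low, high)


@dataclass(frozen=True)
class Fingerprint:
    """A genotype map over a fixed marker panel, with provenance.

    ``weight`` is the fingerprint's share in hierarchical merging
    (1/(i*j*k*m) at the experiment layer); ``provenance`` lists the entity
    ids the fingerprint was merged from (itself, for raw uploads). ``name``
    and ``synonyms`` support homonymy-scoped comparison; ``image_refs``
    holds per-marker CE image file paths (path indirection only).
    """

    entity_id: str
    layer: Layer
    genotypes: Mapping[str, LocusGenotype]
    weight: float = 1.0
    provenance: tuple[str, ...] = ()
    name: str = ""
    synonyms: tuple[str, ...] = ()
    image_refs: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        for marker_id, g in self.genotypes.items():
            if g.marker_id != marker_id:
                raise ValueError(f"genotype keyed {marker_id} carries {g.marker_id}")
        if not self.provenance:
            object.__setattr__(self, "provenance", (self.entity_id,))

    @property
    def p(self) -> int:
        """Panel size (total loci)."""
        return len(self.genotypes)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def effective_count(self) -> int:
        return sum(1 for g in self.genotypes.values() if not g.is_missing)

    def with_weight(self, weight: float) -> "Fingerprint":
        return replace(self, weight=weight)

    def names(self) -> frozenset[str]:
        """Trimmed name + synonyms, for homonymy matching."""
        out = {self.name.strip()} | {s.strip() for s in self.synonyms}
        out.discard("")
        return frozenset(out)


@dataclass(frozen=True)
class HierarchyIndex:
    """Replicate counts of the merge hierarchy.

    i: experiments per DNA solution; j: DNA extractions per experimenter per
    sample; k: experimenters per sample; m: samples per variety. Set m=1 to
    treat each sample as an independent variety.
    """

    i: int = 3
    j: int = 1
    k: int = 1
    m: int = 1

    def __post_init__(self) -> None:
        for name in ("i", "j", "k", "m"):
            if getattr(self, name) < 1:
                raise ValueError(f"hierarchy count {name} must be >= 1")

    @property
    def leaf_weight(self) -> float:
        return 1.0 / (self.i * self.j * self.k * self.m)


@dataclass(frozen=True)
class ComparisonParams:
    """Tuning parameters of the fingerprint comparison algorithm.

    base_offset_bp
        Maximum allele-size difference (bp) tolerated when two alleles are
        declared identical; absorbs the 1-2 bp CE read error. Range [0, 2],
        default 2.
    min_comparison_loci
        Floor on the number of shared non-missing loci (p - M) for a result
        to be reported. Default 20.
    max_diff_loci
        Ceiling on the different-locus count D. Default 20.
    max_diff_fraction
        Ceiling on the different-locus fraction x = D/p. Default 0.05.
    """

    base_offset_bp: float = 2.0
    min_comparison_loci: int = 20
    max_diff_loci: int = 20
    max_diff_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_offset_bp <= 2.0:
            raise ValueError(
                f"base_offset_bp must be in [0, 2] bp, got {self.base_offset_bp}"
            )
        if self.min_comparison_loci < 0:
            raise ValueError("min_comparison_loci must be >= 0")
        if self.max_diff_loci < 0:
            raise ValueError("max_diff_loci must be >= 0")
        if not 0.0 <= self.max_diff_fraction <= 1.0:
            raise ValueError("max_diff_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-pair locus tallies: p = D + S + M, x = D/p.

    D different, S non-different, M missing loci over a panel of p; x is the
    differential-locus fraction — the larger x, the greater the genotyping
    difference between the pair.
    """

    id_pending: str
    id_reference: str
    p: int
    D: int
    S: int
    M: int
    x: float

    def __post_init__(self) -> None:
        if self.p != self.D + self.S + self.M:
            raise ValueError(
                f"locus counts do not conserve: p={self.p} != "
                f"D+S+M={self.D + self.S + self.M}"
            )
        if self.p > 0 and self.x != self.D / self.p:
            raise ValueError(f"x={self.x} != D/p={self.D / self.p}")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"x out of [0, 1]: {self.x}")

    @classmethod
    def from_counts(
        cls, id_pending: str, id_reference: str, p: int, D: int, S: int, M: int
    ) -> "ComparisonResult":
        return cls(id_pending, id_reference, p, D, S, M, D / p if p else 0.0)

    @property
    def shared_loci(self) -> int:
        """Loci effective on both sides (p - M)."""
        return self.p - self.M


def validate_fingerprint(fp: Fingerprint, panel: Sequence[MarkerDef]) -> list[str]:
    """Check a fingerprint against its panel; violations are data, not errors.

    Returns an empty list iff every panel marker is present as a key and
    every effective allele lies within the marker's expected size range.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    violations: list[str] = []
    by_id = {m.marker_id: m for m in panel}
    for marker in by_id:
        if marker not in fp.genotypes:
            violations.append(f"{fp.entity_id}: panel marker {marker} absent")
    for marker_id, g in fp.genotypes.items():
        mdef = by_id.get(marker_id)
        if mdef is None:
            violations.append(f"{fp.entity_id}: marker {marker_id} not in panel")
            continue
        if g.is_missing:
            continue
        for a in g.alleles:
            if not mdef.size_min <= a <= mdef.size_max:
                violations.append(
                    f"{fp.entity_id}: {marker_id} allele {a} outside "
                    f"[{mdef.size_min}, {mdef.size_max}]"
                )
    return violations


def check_shared_panel(fps: Iterable[Fingerprint]) -> tuple[str, ...]:
    """Assert all fingerprints cover one panel; return its marker tuple."""
    markers: tuple[str, ...] | None = None
    for fp in fps:
        if markers is None:
            markers = fp.markers
        elif set(fp.markers) != set(markers):
            raise ValueError(
                f"fingerprint {fp.entity_id} covers a different panel "
                f"({len(fp.markers)} vs {len(markers)} markers)"
            )
    if markers is None:
        raise ValueError("no fingerprints supplied")
    return markers
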