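"""Offset-tolerant fingerprint comparison.

Two diploid genotypes are "same" when either the direct or the crossed
allele pairing agrees within the base offset (the genotype comparison at
one locus, :func:`gca`). A pairwise queue comparison (:func:`fcpp`) scores
every pending x reference fingerprint pair by its locus tallies, and
results are filtered by the standard reporting thresholds.

Comparison scope is selected by mode: the whole reference database,
entries sharing the pending fingerprint's name or synonyms (homonymy), the
complement of that set, an externally assigned sub-database, or explicit
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .core import (
    ComparisonParams,
    ComparisonResult,
    Fingerprint,
    LocusGenotype,
    check_shared_panel,
)


class LocusClass(str, Enum):
    SAME = "SAME"
    DIFFERENT = "DIFFERENT"
    MISSING = "MISSING"


class Mode(str, Enum):
    DATABASE = "DATABASE"
    HOMONYMY = "HOMONYMY"
    NON_HOMONYMY = "NON_HOMONYMY"
    SUB_DATABASE = "SUB_DATABASE"
    PAIRED = "PAIRED"


def gca(g1: LocusGenotype, g2: LocusGenotype, n: float) -> int:
    """Genotype comparison at one locus; 0 = same, 1 = different.

    With genotypes [a1, b1] and [a2, b2], the pair is "same" iff the direct
    pairing (|a1-a2| <= n and |b1-b2| <= n) or the crossed pairing
    (|a1-b2| <= n and |a2-b1| <= n) holds, where n is the allowed offset in
    bp. Both inputs must be effective; classify missing loci first.
    """
    if n < 0:
        raise ValueError(f"offset n must be >= 0, got {n}")
    if g1.is_missing or g2.is_missing:
        raise ValueError("gca requires two effective genotypes")
    a1, b1 = g1.alleles
    a2, b2 = g2.alleles
    direct = abs(a1 - a2) <= n and abs(b1 - b2) <= n
    crossed = abs(a1 - b2) <= n and abs(a2 - b1) <= n
    return 0 if direct or crossed else 1


def classify_locus(g1: LocusGenotype, g2: LocusGenotype, n: float) -> LocusClass:
    """MISSING if either call is missing, else SAME/DIFFERENT by :func:`gca`.

    A locus is missing for the pair when fewer than two effective calls are
    available at it.
    """
    if g1.marker_id != g2.marker_id:
        raise ValueError(f"marker mismatch: {g1.marker_id} vs {g2.marker_id}")
    if g1.is_missing or g2.is_missing:
        return LocusClass.MISSING
    return LocusClass.SAME if gca(g1, g2, n) == 0 else LocusClass.DIFFERENT


def compare_pair(
    f1: Fingerprint, f2: Fingerprint, params: ComparisonParams | None = None
) -> ComparisonResult:
    """Tally D/S/M over the shared panel; f1 is pending, f2 reference."""
    params = params or ComparisonParams()
    if set(f1.markers) != set(f2.markers):
        raise ValueError(
            f"panel mismatch between {f1.entity_id} and {f2.entity_id}"
        )
    D = S = M = 0
    for marker in f1.markers:
        cls = classify_locus(
            f1.genotypes[marker], f2.genotypes[marker], params.base_offset_bp
        )
        if cls is LocusClass.MISSING:
            M += 1
        elif cls is LocusClass.SAME:
            S += 1
        else:
            D += 1
    return ComparisonResult.from_counts(f1.entity_id, f2.entity_id, f1.p, D, S, M)


def fcpp(
    pending: Sequence[Fingerprint],
    reference: Sequence[Fingerprint],
    params: ComparisonParams | None = None,
) -> list[ComparisonResult]:
    """Pairwise queue comparison: every ordered (pending, reference) pair.

    Returns exactly ``len(reference) * len(pending)`` results, ordered
    reference-major then pending (the outer loop walks the reference
    queue).
    """
    if not pending or not reference:
        raise ValueError("both comparison queues must be non-empty")
    check_shared_panel(list(pending) + list(reference))
    params = params or ComparisonParams()
    results: list[ComparisonResult] = []
    for ref in reference:
        for pend in pending:
            results.append(compare_pair(pend, ref, params))
    return results


def filter_results(
    results: Sequence[ComparisonResult], params: ComparisonParams | None = None
) -> list[ComparisonResult]:
    """Keep results worth reporting under the configured thresholds.

    A result survives iff its shared non-missing loci (p - M) reach
    ``min_comparison_loci``, D does not exceed ``max_diff_loci`` and x does
    not exceed ``max_diff_fraction``.
    """
    params = params or ComparisonParams()
    return [
        r
        for r in results
        if r.shared_loci >= params.min_comparison_loci
        and r.D <= params.max_diff_loci
        and r.x <= params.max_diff_fraction
    ]


@dataclass(frozen=True)
class ComparisonPlan:
    """Resolved scope of one comparison run.

    For cross-product modes ``pairs`` is None and every pending x reference
    combination is scored; PAIRED mode carries aligned explicit pairs.
    """

    pending: tuple[Fingerprint, ...]
    reference: tuple[Fingerprint, ...]
    pairs: tuple[tuple[Fingerprint, Fingerprint], ...] | None = None

    def run(self, params: ComparisonParams | None = None) -> list[ComparisonResult]:
        params = params or ComparisonParams()
        if self.pairs is not None:
            return [compare_pair(p, r, params) for p, r in self.pairs]
        return fcpp(list(self.pending), list(self.reference), params)


def _lfd_of(store) -> list[Fingerprint]:
    if hasattr(store, "lfd_fingerprints"):
        return list(store.lfd_fingerprints())
    return list(store)


def select_scope(
    mode: Mode,
    store,
    pending: Sequence[Fingerprint],
    assignment: "Assignment | None" = None,
) -> ComparisonPlan:
    """Resolve the pending and reference queues for a comparison mode.

    ``store`` is either a fingerprint store exposing ``lfd_fingerprints()``
    or a plain sequence standing in for the reference database. Homonymy
    matches on trimmed, case-sensitive equality of any name/synonym of a
    reference entry against any pending name; the non-homonymy scope is its
    exact complement, so the two partition the database.
    """
    mode = Mode(mode)
    if mode in (Mode.SUB_DATABASE, Mode.PAIRED):
        if assignment is None:
            raise ValueError(f"{mode.value} comparison requires an assignment")
    elif assignment is not None:
        raise ValueError(f"{mode.value} comparison forbids an assignment")

    if mode is Mode.PAIRED:
        by_id = {fp.entity_id: fp for fp in pending}
        by_id.update({fp.entity_id: fp for fp in _lfd_of(store)})
        pairs = []
        for pend_id, ref_id in assignment.pairs:  # type: ignore[union-attr]
            try:
                pairs.append((by_id[pend_id], by_id[ref_id]))
            except KeyError as e:
                raise KeyError(f"assigned fingerprint {e.args[0]} not found") from None
        return ComparisonPlan(
            tuple(p for p, _ in pairs), tuple(r for _, r in pairs), tuple(pairs)
        )

    if mode is Mode.SUB_DATABASE:
        by_id = {fp.entity_id: fp for fp in pending}
        by_id.update({fp.entity_id: fp for fp in _lfd_of(store)})
        pend = tuple(by_id[i] for i in assignment.pending_ids)  # type: ignore[union-attr]
        ref = tuple(by_id[i] for i in assignment.reference_ids)  # type: ignore[union-attr]
        return ComparisonPlan(pend, ref)

    lfd = _lfd_of(store)
    if not lfd:
        raise ValueError("reference fingerprint database is empty")
    if mode is Mode.DATABASE:
        return ComparisonPlan(tuple(pending), tuple(lfd))

    pending_names: set[str] = set()
    for fp in pending:
        pending_names |= fp.names()
    homonyms = tuple(fp for fp in lfd if fp.names() & pending_names)
    if mode is Mode.HOMONYMY:
        return ComparisonPlan(tuple(pending), homonyms)
    others = tuple(fp for fp in lfd if not (fp.names() & pending_names))
    return ComparisonPlan(tuple(pending), others)


@dataclass(frozen=True)
class Assignment:
    """External scope assignment for sub-database and paired comparison."""

    pending_ids: tuple[str, ...] = ()
    reference_ids: tuple[str, ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()


def read_assignment(path, mode: Mode) -> Assignment:
    """Load a scope assignment from CSV/XLSX.

    PAIRED expects columns ``pending_id, reference_id``; SUB_DATABASE
    expects ``member_id, role`` with roles PENDING/REFERENCE.
    """
    mode = Mode(mode)
    reader = pd.read_excel if str(path).endswith((".xlsx", ".xls")) else pd.read_csv
    df = reader(path, dtype=str)
    if mode is Mode.PAIRED:
        missing = {"pending_id", "reference_id"} - set(df.columns)
        if missing:
            raise ValueError(f"paired assignment missing columns: {sorted(missing)}")
        return Assignment(
            pairs=tuple(zip(df["pending_id"].tolist(), df["reference_id"].tolist()))
        )
    if mode is Mode.SUB_DATABASE:
        missing = {"member_id", "role"} - set(df.columns)
        if missing:
            raise ValueError(f"sub-database assignment missing columns: {sorted(missing)}")
        roles = df["role"].str.upper()
        return Assignment(
            pending_ids=tuple(df.loc[roles == "PENDING", "member_id"]),
            reference_ids=tuple(df.loc[roles == "REFERENCE", "member_id"]),
        )
    raise ValueError(f"no assignment format for mode {mode.value}")


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison report as a table: one row per pair with a verdict.

    The verdict marks pairs that are indistinguishable at the locus level
    (no different loci among the shared ones).
    """
    rows = [
        {
            "pending_id": r.id_pending,
            "reference_id": r.id_reference,
            "p": r.p,
            "D": r.D,
            "S": r.S,
            "M": r.M,
            "x": r.x,
            "verdict": "match" if r.D == 0 else "distinct",
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["pending_id", "reference_id", "p", "D", "S", "M", "x", "verdict"]
    )
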