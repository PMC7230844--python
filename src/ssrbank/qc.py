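"""Experiment-level quality control.

Three complementary checks:

* **Reference-sample check** — standard samples run alongside the plate
  are compared against their stored standard fingerprints; any different
  locus marks the whole run as suspect (an overall detection error such as
  a ladder or dye failure).
* **Replicate audit** — the repeated experiments of each sample (three is
  canonical) are consensus-merged; flagged or missing loci quantify the
  basic quality of the experiment.
* **Noise-tolerance scan** — synthetic replicate sets with a controlled
  proportion of whole noise replicates establish the boundary below which
  the automated audit preserves every effective locus. With the default
  effective-data rule this boundary is 40% for odd replicate counts: a
  minority of strictly less than 40% noise never reduces the merged
  effective-locus count, while 40% or more does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np

from .core import ComparisonParams, Fingerprint, Layer, MarkerDef
from .compare import compare_pair
from .merge import EFFECTIVE_SUPPORT_THRESHOLD, MergeOutcome, peer_merge
from . import synth


@dataclass(frozen=True)
class ReferenceCheck:
    reference_id: str
    standard_id: str
    D: int
    M: int
    passed: bool


@dataclass(frozen=True)
class ReplicateAudit:
    sample_id: str
    n_replicates: int
    effective_loci: int
    flagged_loci: int
    missing_loci: int
    consistent: bool


@dataclass(frozen=True)
class NoiseScanPoint:
    replicates: int
    requested_fraction: float
    realized_fraction: float
    effective_before: int
    effective_after: int
    degraded: bool


@dataclass
class QCReport:
    """Aggregated QC findings; any failing fragment marks the run suspect."""

    reference_checks: list[ReferenceCheck] = field(default_factory=list)
    replicate_audits: list[ReplicateAudit] = field(default_factory=list)
    noise_scan: list[NoiseScanPoint] = field(default_factory=list)
    noise_threshold_percent: float | None = None

    @property
    def run_suspect(self) -> bool:
        return any(not c.passed for c in self.reference_checks)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def to_text(self) -> str:
        lines = []
        for c in self.reference_checks:
            lines.append(
                f"reference {c.reference_id} vs standard {c.standard_id}: "
                f"D={c.D} M={c.M} -> {'pass' if c.passed else 'FAIL'}"
            )
        if self.reference_checks:
            lines.append(
                "run status: " + ("SUSPECT" if self.run_suspect else "clean")
            )
        for a in self.replicate_audits:
            lines.append(
                f"sample {a.sample_id}: {a.n_replicates} replicates, "
                f"{a.effective_loci} effective, {a.flagged_loci} flagged, "
                f"{a.missing_loci} missing -> "
                f"{'consistent' if a.consistent else 'inconsistent'}"
            )
        if self.noise_threshold_percent is not None:
            lines.append(
                f"noise tolerance boundary: {self.noise_threshold_percent:g}%"
            )
        return "\n".join(lines)


def reference_check(
    run_references: Mapping[str, Fingerprint],
    standards: Mapping[str, Fingerprint],
    params: ComparisonParams | None = None,
) -> QCReport:
    """Compare each in-run reference sample against its stored standard.

    A check passes iff D = 0 at the default offset; any failure flags the
    whole run (detail per reference is retained for diagnosis).
    """
    params = params or ComparisonParams()
    report = QCReport()
    for ref_id, fp in run_references.items():
        if ref_id not in standards:
            raise KeyError(f"no stored standard fingerprint for reference {ref_id}")
        r = compare_pair(fp, standards[ref_id], params)
        report.reference_checks.append(
            ReferenceCheck(ref_id, standards[ref_id].entity_id, r.D, r.M, r.D == 0)
        )
    return report


def replicate_audit(
    replicate_sets: Mapping[str, Sequence[Fingerprint]],
    offset: float = 2.0,
    effective_threshold: float = EFFECTIVE_SUPPORT_THRESHOLD,
) -> tuple[QCReport, dict[str, MergeOutcome]]:
    """Consensus-audit each sample's repeated experiments.

    Consistent replicate sets yield zero flagged loci. A single replicate
    is trivially consistent (nothing to cross-check) and is reported as
    such rather than rejected.
    """
    report = QCReport()
    outcomes: dict[str, MergeOutcome] = {}
    for sample_id, fps in replicate_sets.items():
        if not fps:
            raise ValueError(f"sample {sample_id} has no replicates")
        fps = [fp.with_weight(1.0 / len(fps)) for fp in fps]
        out = peer_merge(fps, offset, effective_threshold, merged_id=sample_id)
        flagged = len(out.flagged())
        merged = out.merged
        report.replicate_audits.append(
            ReplicateAudit(
                sample_id=sample_id,
                n_replicates=len(fps),
                effective_loci=merged.effective_count(),
                flagged_loci=flagged,
                missing_loci=merged.p - merged.effective_count(),
                consistent=flagged == 0,
            )
        )
        outcomes[sample_id] = out
    return report, outcomes


def noise_tolerance_scan(
    panel: Sequence[MarkerDef] | None = None,
    replicate_counts: Sequence[int] = (3, 5, 7),
    noise_fractions: Sequence[float] = (0.2, 1 / 3, 0.4, 3 / 7, 0.6),
    seed: int = 0,
    n_markers: int = 20,
    offset: float = 2.0,
    effective_threshold: float = EFFECTIVE_SUPPORT_THRESHOLD,
) -> QCReport:
    """Map the noise boundary of the automated replicate audit.

    For each odd replicate count r and noise proportion f, a replicate set
    of ``round(f*r)`` whole noise fingerprints plus exact truth copies is
    merged, and the scan records whether the merged effective-locus count
    dropped below the panel size. The reported threshold is the largest
    noise percentage strictly below which no configuration degrades, i.e.
    the smallest realized noise fraction that does.
    """
    for r in replicate_counts:
        if r % 2 == 0:
            raise ValueError(f"replicate counts must be odd, got {r}")
    for f in noise_fractions:
        if not 0.0 < f < 1.0:
            raise ValueError(f"noise fractions must lie in (0, 1), got {f}")

    rng = np.random.default_rng(seed)
    if panel is None:
        config = synth.SimConfig(n_markers=n_markers, seed=seed)
        panel, truths = synth.generate_truth(config, rng)
        truth = next(iter(truths.values()))
    else:
        genotypes = {
            m.marker_id: synth._draw_genotype(m, rng, 0.5) for m in panel
        }
        truth = Fingerprint("scan-truth", Layer.VARIETY, genotypes)

    report = QCReport()
    p = truth.p
    for r in replicate_counts:
        for f in noise_fractions:
            n_noise = int(round(f * r))
            replicates = [
                Fingerprint(f"clean-{t}", truth.layer, truth.genotypes,
                            weight=1.0 / r)
                for t in range(r - n_noise)
            ] + [
                synth.noise_fingerprint(
                    list(panel), truth, f"noise-{t}", rng, offset
                ).with_weight(1.0 / r)
                for t in range(n_noise)
            ]
            out = peer_merge(replicates, offset, effective_threshold)
            eff = out.merged.effective_count()
            report.noise_scan.append(
                NoiseScanPoint(
                    replicates=r,
                    requested_fraction=f,
                    realized_fraction=n_noise / r,
                    effective_before=p,
                    effective_after=eff,
                    degraded=eff < p,
                )
            )

    degraded = [pt.realized_fraction for pt in report.noise_scan if pt.degraded]
    if degraded:
        report.noise_threshold_percent = round(min(degraded) * 100.0, 6)
    else:
        report.noise_threshold_percent = 100.0
    return report
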