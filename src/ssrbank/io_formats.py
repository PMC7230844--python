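"""File formats: genotype tables, sample information tables, plate layouts.

The canonical genotype table is a long-format CSV in the style of a
GeneMapper genotypes export — one row per (sample, marker) with two allele
columns — and the same mapping is accepted from XLSX. A Sample
Information Table (SIT) declares the sample / experimenter / DNA /
experiment hierarchy an experimenter is responsible for; it is both the
permission boundary for auditing and the scaffold of the merge tree.
Plate design fills 96-well plates deterministically for printable bench
layouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import Fingerprint, Layer, LocusGenotype, MarkerDef, make_genotype
from .merge import DnaNode, ExperimenterNode, MergeTree, SampleNode


@dataclass(frozen=True)
class GenotypeTableDialect:
    """Column mapping of a genotype table."""

    sample_col: str = "Sample Name"
    marker_col: str = "Marker"
    allele1_col: str = "Allele 1"
    allele2_col: str = "Allele 2"
    header: bool = True


CANONICAL_DIALECT = GenotypeTableDialect()


def _read_frame(path, dialect: GenotypeTableDialect) -> pd.DataFrame:
    path = Path(path)
    header = 0 if dialect.header else None
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=header)
    else:
        df = pd.read_csv(path, header=header)
    if not dialect.header:
        df.columns = [
            dialect.sample_col, dialect.marker_col,
            dialect.allele1_col, dialect.allele2_col,
        ][: len(df.columns)]
    needed = {dialect.sample_col, dialect.marker_col,
              dialect.allele1_col, dialect.allele2_col}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    return df


def read_genotype_table(
    path,
    panel: Sequence[MarkerDef],
    dialect: GenotypeTableDialect = CANONICAL_DIALECT,
    duplicate_single_allele: bool = False,
    layer: Layer = Layer.EXPERIMENT,
) -> list[Fingerprint]:
    """Parse a genotype table into one fingerprint per sample.

    Rows with both allele cells blank become MISSING loci, as do panel
    markers absent for a sample. A row with exactly one allele is rejected
    (half-called loci are not diploid genotypes) unless
    ``duplicate_single_allele`` is set, in which case the single call is
    duplicated into a homozygote.
    """
    df = _read_frame(path, dialect)
    panel_ids = [m.marker_id for m in panel]
    bad_rows = df[~df[dialect.marker_col].astype(str).isin(panel_ids)]
    if len(bad_rows):
        raise ValueError(
            "unknown markers vs panel in rows: "
            + ", ".join(
                f"{r[dialect.sample_col]}/{r[dialect.marker_col]}"
                for _, r in bad_rows.iterrows()
            )
        )
    fps: list[Fingerprint] = []
    for sample_id, group in df.groupby(dialect.sample_col, sort=False):
        genotypes: dict[str, LocusGenotype] = {
            m: LocusGenotype(m) for m in panel_ids
        }
        for _, row in group.iterrows():
            marker = str(row[dialect.marker_col])
            alleles = [
                float(row[c])
                for c in (dialect.allele1_col, dialect.allele2_col)
                if pd.notna(row[c]) and str(row[c]).strip() != ""
            ]
            if len(alleles) == 1:
                if not duplicate_single_allele:
                    raise ValueError(
                        f"{sample_id}/{marker}: one allele called; "
                        "pass duplicate_single_allele=True to store as homozygote"
                    )
                alleles = alleles * 2
            genotypes[marker] = make_genotype(marker, alleles)
        fps.append(
            Fingerprint(str(sample_id), layer, genotypes, name=str(sample_id))
        )
    return fps


def write_genotype_table(
    fps: Sequence[Fingerprint],
    path,
    panel: Sequence[MarkerDef] | None = None,
    dialect: GenotypeTableDialect = CANONICAL_DIALECT,
) -> None:
    """Write fingerprints in the canonical long format.

    Row order is deterministic: samples in input order, markers in panel
    order. Missing loci get blank allele cells; homozygotes repeat the
    size in both columns. Round-trips through
    :func:`read_genotype_table`.
    """
    markers = [m.marker_id for m in panel] if panel else (
        list(fps[0].markers) if fps else []
    )
    rows = []
    for fp in fps:
        for marker in markers:
            g = fp.genotypes[marker]
            rows.append(
                {
                    dialect.sample_col: fp.entity_id,
                    dialect.marker_col: marker,
                    dialect.allele1_col: "" if g.is_missing else g.allele_low,
                    dialect.allele2_col: "" if g.is_missing else g.allele_high,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[dialect.sample_col, dialect.marker_col,
                 dialect.allele1_col, dialect.allele2_col],
    )
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def write_panel(panel: Sequence[MarkerDef], path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id, "panel_id": m.panel_id,
                "repeat_unit": m.repeat_unit,
                "size_min": m.size_min, "size_max": m.size_max,
            }
            for m in panel
        ]
    ).to_csv(path, index=False)


def read_panel(path) -> list[MarkerDef]:
    df = pd.read_csv(path)
    return [
        MarkerDef(str(r.marker_id), str(r.panel_id), int(r.repeat_unit),
                  float(r.size_min), float(r.size_max))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Sample Information Table


@dataclass(frozen=True)
class SitRow:
    sample_id: str
    variety: str
    experimenter_id: str
    dna_id: str
    experiment_id: str
    plant_id: str = ""


@dataclass
class SIT:
    """The sample/experimenter/DNA/experiment hierarchy one upload declares.

    Multiple DNA extractions by the same experimenter from one plant are
    one repeat: such rows are collapsed into a single DNA node when the
    merge tree is built.
    """

    rows: list[SitRow]
    sit_id: str = "SIT"

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.sample_id)
        return list(seen)

    def varieties(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.variety)
        return list(seen)

    def _dna_key(self, row: SitRow) -> str:
        # same experimenter + same plant -> one DNA node regardless of
        # how the extractions were numbered
        return row.plant_id if row.plant_id else row.dna_id

    def build_tree(
        self,
        fingerprints: Mapping[str, Fingerprint],
        variety: str | None = None,
    ) -> MergeTree:
        """Assemble the merge tree for one variety from experiment
        fingerprints keyed by experiment_id."""
        varieties = self.varieties()
        if variety is None:
            if len(varieties) != 1:
                raise ValueError(
                    f"SIT covers {len(varieties)} varieties; specify one"
                )
            variety = varieties[0]
        rows = [r for r in self.rows if r.variety == variety]
        if not rows:
            raise ValueError(f"variety {variety} not in SIT")
        samples: dict[str, dict[str, dict[str, list[SitRow]]]] = {}
        for r in rows:
            samples.setdefault(r.sample_id, {}).setdefault(
                r.experimenter_id, {}
            ).setdefault(self._dna_key(r), []).append(r)
        sample_nodes = []
        for sample_id, expers in samples.items():
            exper_nodes = []
            for exper_id, dnas in expers.items():
                dna_nodes = []
                for dna_key, dna_rows in dnas.items():
                    leaves = []
                    for r in dna_rows:
                        if r.experiment_id not in fingerprints:
                            raise KeyError(
                                f"no fingerprint for experiment {r.experiment_id}"
                            )
                        leaves.append(fingerprints[r.experiment_id])
                    dna_nodes.append(DnaNode(f"{exper_id}:{dna_key}", leaves))
                exper_nodes.append(ExperimenterNode(exper_id, dna_nodes))
            sample_nodes.append(SampleNode(sample_id, exper_nodes))
        return MergeTree(variety, sample_nodes)

    def sample_tree(
        self, sample_id: str, fingerprints: Mapping[str, Fingerprint]
    ) -> MergeTree:
        """Single-sample tree (m = 1): the sample audited as its own variety."""
        rows = [r for r in self.rows if r.sample_id == sample_id]
        if not rows:
            raise KeyError(f"sample {sample_id} not in SIT")
        sub = SIT(rows, self.sit_id)
        tree = sub.build_tree(fingerprints, variety=rows[0].variety)
        tree.variety_id = sample_id
        return tree


SIT_COLUMNS = ["sample_id", "variety", "experimenter_id", "dna_id", "experiment_id"]


def read_sit(path, sit_id: str | None = None) -> SIT:
    """Load a SIT from CSV/XLSX; ``plant_id`` is an optional extra column."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    missing = set(SIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SIT missing columns: {sorted(missing)}")
    dupes = df["experiment_id"][df["experiment_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate experiment ids in SIT: {sorted(set(dupes))}")
    rows = [
        SitRow(
            sample_id=str(r["sample_id"]),
            variety=str(r["variety"]),
            experimenter_id=str(r["experimenter_id"]),
            dna_id=str(r["dna_id"]),
            experiment_id=str(r["experiment_id"]),
            plant_id=str(r["plant_id"]) if "plant_id" in df.columns and pd.notna(r.get("plant_id")) else "",
        )
        for _, r in df.iterrows()
    ]
    return SIT(rows, sit_id or path.stem)


def write_sit(sit: SIT, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id, "variety": r.variety,
            "experimenter_id": r.experimenter_id, "dna_id": r.dna_id,
            "experiment_id": r.experiment_id, "plant_id": r.plant_id,
        }
        for r in sit.rows
    ]
    pd.DataFrame(rows, columns=SIT_COLUMNS + ["plant_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plate design

WELL_ROWS = "ABCDEFGH"
WELL_COLS = range(1, 13)
WELLS_96 = [f"{r}{c}" for r in WELL_ROWS for c in WELL_COLS]


@dataclass(frozen=True)
class WellAssignment:
    sample_id: str
    dna_id: str
    panel_id: str
    role: str  # SAMPLE | REFERENCE | BLANK


@dataclass
class PlateLayout:
    barcode: str
    wells: dict[str, WellAssignment] = field(default_factory=dict)

    def assign(self, well: str, job: WellAssignment) -> None:
        if well not in WELLS_96:
            raise ValueError(f"unknown well {well}")
        if well in self.wells:
            raise ValueError(f"well {well} on plate {self.barcode} double-booked")
        self.wells[well] = job

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"barcode": self.barcode, "well": w, "sample_id": a.sample_id,
             "dna_id": a.dna_id, "panel_id": a.panel_id, "role": a.role}
            for w, a in self.wells.items()
        ]
        return pd.DataFrame(
            rows, columns=["barcode", "well", "sample_id", "dna_id", "panel_id", "role"]
        )


def design_plates(
    jobs: Sequence[tuple[str, str, str]],
    refs_per_plate: int = 1,
    barcode_prefix: str = "PLT",
) -> list[PlateLayout]:
    """Deterministic row-major fill of 96-well plates.

    The first ``refs_per_plate`` wells of every plate are reserved for
    reference (standard) samples; jobs — (sample_id, dna_id, panel_id)
    triples — fill the remaining wells A1-H12 in order. The number of
    plates is ``ceil(len(jobs) / (96 - refs_per_plate))``.
    """
    if not jobs:
        raise ValueError("no jobs to plate")
    if refs_per_plate >= 96:
        raise ValueError("refs_per_plate must leave room for samples")
    usable = 96 - refs_per_plate
    n_plates = math.ceil(len(jobs) / usable)
    plates = []
    it = iter(jobs)
    for n in range(n_plates):
        plate = PlateLayout(f"{barcode_prefix}{n + 1:04d}")
        for idx, well in enumerate(WELLS_96):
            if idx < refs_per_plate:
                plate.assign(well, WellAssignment("REF", "", "", "REFERENCE"))
                continue
            job = next(it, None)
            if job is None:
                break
            sample_id, dna_id, panel_id = job
            plate.assign(well, WellAssignment(sample_id, dna_id, panel_id, "SAMPLE"))
        plates.append(plate)
    return plates


def plates_to_frame(plates: Sequence[PlateLayout]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in plates], ignore_index=True)
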