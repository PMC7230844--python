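"""Three-tier audited fingerprint store (EFD -> SFD -> LFD).

Raw uploads land in the Experimental Fingerprint Database (EFD) and are
never altered. Auditing a Sample Information Table runs the hierarchical
merge over each sample's replicates and writes the per-sample consensus to
the Sample Fingerprint Database (SFD); samples with unresolved audit flags
stay unaudited there until a manual reselection. Audited sample
fingerprints are promoted to the Local Fingerprint Database (LFD), the
reference store used by comparison and reporting, where records can be
locked and become immutable.

The store is a single-file embedded relational database (SQLite) whose
tables mirror the bench bookkeeping — samples, DNA extractions,
experimenters, plates and wells — while fingerprint payloads and CE image
references live in sidecar JSON files referenced by path, keeping bulky
and crop-specific data out of the tables.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import Fingerprint, Layer, LocusGenotype, MarkerDef, validate_fingerprint
from .io_formats import SIT, PlateLayout, SitRow
from .merge import CrossLayerResult, MergeOutcome, cross_layer_merge

__all__ = [
    "FingerprintStore", "StoreError", "StorePermissionError",
    "ImmutableRecordError", "RecordNotFoundError", "AuditResult",
]


class StoreError(Exception):
    pass


class StorePermissionError(StoreError):
    pass


class ImmutableRecordError(StoreError):
    pass


class RecordNotFoundError(StoreError):
    pass


_SCHEMA = """
PRAGMA foreign_keys = ON;

CREATE TABLE IF NOT EXISTS experimenter (
    experimenter_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS variety (
    variety_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS sample (
    sample_id TEXT PRIMARY KEY,
    variety_id TEXT REFERENCES variety(variety_id)
);
CREATE TABLE IF NOT EXISTS dna (
    dna_id TEXT PRIMARY KEY,
    sample_id TEXT REFERENCES sample(sample_id),
    experimenter_id TEXT REFERENCES experimenter(experimenter_id),
    plant_id TEXT
);
CREATE TABLE IF NOT EXISTS panel (
    panel_id TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS marker (
    marker_id TEXT PRIMARY KEY,
    panel_id TEXT NOT NULL REFERENCES panel(panel_id),
    repeat_unit INTEGER NOT NULL,
    size_min REAL NOT NULL,
    size_max REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS sit (
    sit_id TEXT PRIMARY KEY,
    owner_experimenter_id TEXT NOT NULL REFERENCES experimenter(experimenter_id)
);
CREATE TABLE IF NOT EXISTS sit_row (
    sit_id TEXT NOT NULL REFERENCES sit(sit_id),
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    variety_id TEXT NOT NULL REFERENCES variety(variety_id),
    experimenter_id TEXT NOT NULL REFERENCES experimenter(experimenter_id),
    dna_id TEXT NOT NULL REFERENCES dna(dna_id),
    experiment_id TEXT NOT NULL,
    plant_id TEXT,
    UNIQUE (sit_id, experiment_id)
);
CREATE TABLE IF NOT EXISTS pcr (
    pcr_plate_id TEXT PRIMARY KEY,
    barcode TEXT UNIQUE NOT NULL
);
CREATE TABLE IF NOT EXISTS pcr_well (
    pcr_plate_id TEXT NOT NULL REFERENCES pcr(pcr_plate_id),
    well TEXT NOT NULL,
    sample_id TEXT,
    dna_id TEXT,
    panel_id TEXT,
    role TEXT NOT NULL,
    PRIMARY KEY (pcr_plate_id, well)
);
CREATE TABLE IF NOT EXISTS ce (
    ce_plate_id TEXT PRIMARY KEY,
    barcode TEXT UNIQUE NOT NULL,
    pcr_plate_id TEXT REFERENCES pcr(pcr_plate_id)
);
CREATE TABLE IF NOT EXISTS ce_well (
    ce_plate_id TEXT NOT NULL REFERENCES ce(ce_plate_id),
    well TEXT NOT NULL,
    pcr_plate_id TEXT,
    pcr_well TEXT,
    PRIMARY KEY (ce_plate_id, well)
);
CREATE TABLE IF NOT EXISTS fingerprint_file (
    file_id INTEGER PRIMARY KEY AUTOINCREMENT,
    path TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS efd_record (
    record_id TEXT PRIMARY KEY,
    experiment_id TEXT,
    dna_id TEXT,
    owner_experimenter_id TEXT NOT NULL REFERENCES experimenter(experimenter_id),
    file_id INTEGER NOT NULL REFERENCES fingerprint_file(file_id),
    state TEXT NOT NULL DEFAULT 'UNAUDITED',
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS sfd_record (
    record_id TEXT PRIMARY KEY,
    sample_id TEXT NOT NULL,
    file_id INTEGER NOT NULL REFERENCES fingerprint_file(file_id),
    state TEXT NOT NULL DEFAULT 'UNAUDITED',
    auditor TEXT,
    audited_at TEXT
);
CREATE TABLE IF NOT EXISTS sfd_source (
    sfd_id TEXT NOT NULL REFERENCES sfd_record(record_id),
    efd_id TEXT NOT NULL REFERENCES efd_record(record_id)
);
CREATE TABLE IF NOT EXISTS lfd_record (
    record_id TEXT PRIMARY KEY,
    sample_id TEXT NOT NULL,
    file_id INTEGER NOT NULL REFERENCES fingerprint_file(file_id),
    state TEXT NOT NULL DEFAULT 'AUDITED',
    locked INTEGER NOT NULL DEFAULT 0,
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS lfd_source (
    lfd_id TEXT NOT NULL REFERENCES lfd_record(record_id),
    sfd_id TEXT NOT NULL REFERENCES sfd_record(record_id)
);
"""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def fingerprint_to_dict(fp: Fingerprint) -> dict:
    return {
        "entity_id": fp.entity_id,
        "layer": fp.layer.value,
        "genotypes": {
            m: (None if g.is_missing else [g.allele_low, g.allele_high])
            for m, g in fp.genotypes.items()
        },
        "weight": fp.weight,
        "provenance": list(fp.provenance),
        "name": fp.name,
        "synonyms": list(fp.synonyms),
        "image_refs": dict(fp.image_refs) if fp.image_refs else None,
    }


def fingerprint_from_dict(d: Mapping) -> Fingerprint:
    genotypes = {
        m: LocusGenotype(m) if v is None else LocusGenotype(m, v[0], v[1])
        for m, v in d["genotypes"].items()
    }
    return Fingerprint(
        entity_id=d["entity_id"],
        layer=Layer(d["layer"]),
        genotypes=genotypes,
        weight=d.get("weight", 1.0),
        provenance=tuple(d.get("provenance", ())),
        name=d.get("name", ""),
        synonyms=tuple(d.get("synonyms", ())),
        image_refs=d.get("image_refs"),
    )


@dataclass
class AuditResult:
    """Outcome of auditing one SIT: per-sample promotions and blocks."""

    promoted: dict[str, str] = field(default_factory=dict)  # sample -> sfd id
    blocked: dict[str, CrossLayerResult] = field(default_factory=dict)

    @property
    def blocked_samples(self) -> list[str]:
        return list(self.blocked)


class FingerprintStore:
    """Single-file store rooted at a directory.

    Layout: ``store.sqlite`` plus a ``payloads/`` directory of fingerprint
    JSON files referenced by path from the ``fingerprint_file`` table.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.payload_dir = self.root / "payloads"
        self.payload_dir.mkdir(exist_ok=True)
        self.db = sqlite3.connect(self.root / "store.sqlite")
        self.db.row_factory = sqlite3.Row
        self.db.executescript(_SCHEMA)
        self.db.execute("PRAGMA foreign_keys = ON")
        self.db.commit()

    def close(self) -> None:
        self.db.close()

    # -- payload indirection ------------------------------------------------

    def _write_payload(self, record_id: str, fp: Fingerprint) -> int:
        path = self.payload_dir / f"{record_id}.json"
        path.write_text(json.dumps(fingerprint_to_dict(fp), indent=1))
        cur = self.db.execute(
            "INSERT INTO fingerprint_file (path) VALUES (?)",
            (str(path.relative_to(self.root)),),
        )
        return cur.lastrowid

    def _read_payload(self, file_id: int) -> Fingerprint:
        row = self.db.execute(
            "SELECT path FROM fingerprint_file WHERE file_id = ?", (file_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"fingerprint file {file_id}")
        return fingerprint_from_dict(json.loads((self.root / row["path"]).read_text()))

    def _next_id(self, table: str, prefix: str) -> str:
        row = self.db.execute(
            f"SELECT record_id FROM {table} ORDER BY record_id DESC LIMIT 1"
        ).fetchone()
        n = int(row["record_id"].rsplit("-", 1)[1]) if row else 0
        return f"{prefix}-{n + 1:06d}"

    # -- registration -------------------------------------------------------

    def register_panel(self, panel: Sequence[MarkerDef]) -> None:
        for m in panel:
            self.db.execute(
                "INSERT OR IGNORE INTO panel (panel_id) VALUES (?)", (m.panel_id,)
            )
            self.db.execute(
                "INSERT OR REPLACE INTO marker VALUES (?,?,?,?,?)",
                (m.marker_id, m.panel_id, m.repeat_unit, m.size_min, m.size_max),
            )
        self.db.commit()

    def get_panel(self) -> list[MarkerDef]:
        rows = self.db.execute("SELECT * FROM marker ORDER BY marker_id").fetchall()
        if not rows:
            raise StoreError("no panel registered")
        return [
            MarkerDef(r["marker_id"], r["panel_id"], r["repeat_unit"],
                      r["size_min"], r["size_max"])
            for r in rows
        ]

    def register_experimenter(self, experimenter_id: str) -> None:
        self.db.execute(
            "INSERT OR IGNORE INTO experimenter VALUES (?)", (experimenter_id,)
        )
        self.db.commit()

    def register_sit(self, sit: SIT, owner: str) -> None:
        """Store a SIT: hierarchy rows plus the owner permission field."""
        self.register_experimenter(owner)
        self.db.execute(
            "INSERT OR REPLACE INTO sit VALUES (?, ?)", (sit.sit_id, owner)
        )
        for r in sit.rows:
            self.db.execute("INSERT OR IGNORE INTO variety VALUES (?)", (r.variety,))
            self.db.execute(
                "INSERT OR IGNORE INTO sample VALUES (?, ?)", (r.sample_id, r.variety)
            )
            self.db.execute(
                "INSERT OR IGNORE INTO experimenter VALUES (?)", (r.experimenter_id,)
            )
            self.db.execute(
                "INSERT OR IGNORE INTO dna VALUES (?, ?, ?, ?)",
                (r.dna_id, r.sample_id, r.experimenter_id, r.plant_id),
            )
            self.db.execute(
                "INSERT OR REPLACE INTO sit_row VALUES (?,?,?,?,?,?,?)",
                (sit.sit_id, r.sample_id, r.variety, r.experimenter_id,
                 r.dna_id, r.experiment_id, r.plant_id),
            )
        self.db.commit()

    def get_sit(self, sit_id: str) -> tuple[SIT, str]:
        owner_row = self.db.execute(
            "SELECT owner_experimenter_id FROM sit WHERE sit_id = ?", (sit_id,)
        ).fetchone()
        if owner_row is None:
            raise RecordNotFoundError(f"SIT {sit_id}")
        rows = self.db.execute(
            "SELECT * FROM sit_row WHERE sit_id = ?", (sit_id,)
        ).fetchall()
        sit = SIT(
            [
                SitRow(r["sample_id"], r["variety_id"], r["experimenter_id"],
                       r["dna_id"], r["experiment_id"], r["plant_id"] or "")
                for r in rows
            ],
            sit_id,
        )
        return sit, owner_row["owner_experimenter_id"]

    def register_plates(self, plates: Sequence[PlateLayout]) -> None:
        for plate in plates:
            self.db.execute(
                "INSERT OR REPLACE INTO pcr VALUES (?, ?)",
                (plate.barcode, plate.barcode),
            )
            ce_id = f"CE-{plate.barcode}"
            self.db.execute(
                "INSERT OR REPLACE INTO ce VALUES (?, ?, ?)",
                (ce_id, ce_id, plate.barcode),
            )
            for well, a in plate.wells.items():
                self.db.execute(
                    "INSERT OR REPLACE INTO pcr_well VALUES (?,?,?,?,?,?)",
                    (plate.barcode, well, a.sample_id, a.dna_id, a.panel_id, a.role),
                )
                self.db.execute(
                    "INSERT OR REPLACE INTO ce_well VALUES (?,?,?,?)",
                    (ce_id, well, plate.barcode, well),
                )
        self.db.commit()

    # -- EFD ----------------------------------------------------------------

    def submit_efd(
        self,
        fp: Fingerprint,
        owner: str,
        experiment_id: str | None = None,
        dna_id: str | None = None,
    ) -> str:
        """Upload one experiment fingerprint; the original is never altered.

        Repeated uploads of the same experiment create distinct records
        (repeats, not overwrites).
        """
        violations = validate_fingerprint(fp, self.get_panel())
        if violations:
            raise StoreError("invalid fingerprint: " + "; ".join(violations))
        self.register_experimenter(owner)
        record_id = self._next_id("efd_record", "EFD")
        file_id = self._write_payload(record_id, fp)
        self.db.execute(
            "INSERT INTO efd_record VALUES (?,?,?,?,?,?,?)",
            (record_id, experiment_id or fp.entity_id, dna_id, owner, file_id,
             "UNAUDITED", _now()),
        )
        self.db.commit()
        return record_id

    def efd_records(self, owner: str) -> list[str]:
        """Record ids visible to an experimenter (own uploads only)."""
        rows = self.db.execute(
            "SELECT record_id FROM efd_record WHERE owner_experimenter_id = ? "
            "ORDER BY record_id",
            (owner,),
        ).fetchall()
        return [r["record_id"] for r in rows]

    def get_fingerprint(self, tier: str, record_id: str,
                        requester: str | None = None) -> Fingerprint:
        tier = tier.upper()
        table = {"EFD": "efd_record", "SFD": "sfd_record", "LFD": "lfd_record"}[tier]
        row = self.db.execute(
            f"SELECT * FROM {table} WHERE record_id = ?", (record_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"{tier} record {record_id}")
        if tier == "EFD" and requester is not None:
            if row["owner_experimenter_id"] != requester:
                raise StorePermissionError(
                    f"{requester} cannot access EFD data owned by "
                    f"{row['owner_experimenter_id']}"
                )
        return self._read_payload(row["file_id"])

    # -- audit EFD -> SFD ---------------------------------------------------

    def audit_efd_to_sfd(
        self, sit_id: str, auditor: str, offset: float = 2.0
    ) -> AuditResult:
        """Merge each SIT sample's replicates into a sample fingerprint.

        Only the SIT owner may audit. Each sample is merged as its own
        variety (m = 1); samples whose final consensus still carries
        audit flags are stored unaudited and block promotion until
        :meth:`resolve_sample` is called with a manual reselection.
        """
        sit, owner = self.get_sit(sit_id)
        if auditor != owner:
            raise StorePermissionError(
                f"{auditor} does not own SIT {sit_id} (owner: {owner})"
            )
        # experiment_id -> (efd record id, fingerprint)
        by_experiment: dict[str, tuple[str, Fingerprint]] = {}
        for row in self.db.execute("SELECT * FROM efd_record").fetchall():
            by_experiment[row["experiment_id"]] = (
                row["record_id"], self._read_payload(row["file_id"])
            )
        result = AuditResult()
        for sample_id in sit.samples():
            rows = [r for r in sit.rows if r.sample_id == sample_id]
            missing = [r.experiment_id for r in rows if r.experiment_id not in by_experiment]
            if missing:
                raise StoreError(
                    f"sample {sample_id}: EFD records absent for experiments {missing}"
                )
            fps = {eid: by_experiment[eid][1] for eid in (r.experiment_id for r in rows)}
            tree = sit.sample_tree(sample_id, fps)
            merged = cross_layer_merge(tree, offset)
            sfd_id = self._store_sfd(
                sample_id, merged.fingerprint, auditor,
                sources=[by_experiment[r.experiment_id][0] for r in rows],
                audited=not merged.final_outcome.flagged(),
            )
            if merged.final_outcome.flagged():
                result.blocked[sample_id] = merged
            else:
                result.promoted[sample_id] = sfd_id
        return result

    def _store_sfd(self, sample_id: str, fp: Fingerprint, auditor: str,
                   sources: Iterable[str], audited: bool) -> str:
        record_id = self._next_id("sfd_record", "SFD")
        file_id = self._write_payload(record_id, fp)
        self.db.execute(
            "INSERT INTO sfd_record VALUES (?,?,?,?,?,?)",
            (record_id, sample_id, file_id,
             "AUDITED" if audited else "UNAUDITED",
             auditor if audited else None, _now() if audited else None),
        )
        for efd_id in sources:
            self.db.execute(
                "INSERT INTO sfd_source VALUES (?, ?)", (record_id, efd_id)
            )
        self.db.commit()
        return record_id

    def resolve_sample(
        self, sample_id: str, outcome: MergeOutcome, auditor: str
    ) -> str:
        """Replace a blocked sample's draft with a manually resolved merge."""
        if outcome.flagged():
            raise StoreError(
                f"sample {sample_id} still carries audit flags: {outcome.flagged()}"
            )
        row = self.db.execute(
            "SELECT * FROM sfd_record WHERE sample_id = ? AND state = 'UNAUDITED' "
            "ORDER BY record_id DESC",
            (sample_id,),
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"no blocked SFD draft for sample {sample_id}")
        file_id = self._write_payload(row["record_id"] + "-resolved", outcome.merged)
        self.db.execute(
            "UPDATE sfd_record SET file_id = ?, state = 'AUDITED', auditor = ?, "
            "audited_at = ? WHERE record_id = ?",
            (file_id, auditor, _now(), row["record_id"]),
        )
        self.db.commit()
        return row["record_id"]

    # -- SFD -> LFD ---------------------------------------------------------

    def promote_sfd_to_lfd(self, sample_ids: Sequence[str]) -> list[str]:
        """Promote audited sample fingerprints into the reference database."""
        out = []
        for sample_id in sample_ids:
            row = self.db.execute(
                "SELECT * FROM sfd_record WHERE sample_id = ? "
                "ORDER BY record_id DESC",
                (sample_id,),
            ).fetchone()
            if row is None:
                raise RecordNotFoundError(f"no SFD record for sample {sample_id}")
            if row["state"] != "AUDITED":
                raise StoreError(
                    f"sample {sample_id}: SFD record {row['record_id']} is "
                    f"{row['state']}; only audited records can be promoted"
                )
            record_id = self._next_id("lfd_record", "LFD")
            fp = self._read_payload(row["file_id"])
            file_id = self._write_payload(record_id, fp)
            self.db.execute(
                "INSERT INTO lfd_record VALUES (?,?,?,?,?,?)",
                (record_id, sample_id, file_id, "AUDITED", 0, _now()),
            )
            self.db.execute(
                "INSERT INTO lfd_source VALUES (?, ?)", (record_id, row["record_id"])
            )
            out.append(record_id)
        self.db.commit()
        return out

    def lock_lfd(self, record_ids: Sequence[str]) -> None:
        for record_id in record_ids:
            row = self.db.execute(
                "SELECT record_id FROM lfd_record WHERE record_id = ?", (record_id,)
            ).fetchone()
            if row is None:
                raise RecordNotFoundError(f"LFD record {record_id}")
            self.db.execute(
                "UPDATE lfd_record SET locked = 1, state = 'LOCKED' "
                "WHERE record_id = ?",
                (record_id,),
            )
        self.db.commit()

    def update_record(self, tier: str, record_id: str, fp: Fingerprint) -> None:
        """Replace a record's payload; locked records are immutable."""
        tier = tier.upper()
        if tier == "EFD":
            raise StoreError("EFD records are original data and cannot be edited")
        table = {"SFD": "sfd_record", "LFD": "lfd_record"}[tier]
        row = self.db.execute(
            f"SELECT * FROM {table} WHERE record_id = ?", (record_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"{tier} record {record_id}")
        if tier == "LFD" and row["locked"]:
            raise ImmutableRecordError(f"LFD record {record_id} is locked")
        file_id = self._write_payload(record_id + "-edit", fp)
        self.db.execute(
            f"UPDATE {table} SET file_id = ? WHERE record_id = ?",
            (file_id, record_id),
        )
        self.db.commit()

    def delete_record(self, tier: str, record_id: str) -> None:
        tier = tier.upper()
        table = {"EFD": "efd_record", "SFD": "sfd_record", "LFD": "lfd_record"}[tier]
        row = self.db.execute(
            f"SELECT * FROM {table} WHERE record_id = ?", (record_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"{tier} record {record_id}")
        if tier == "LFD":
            if row["locked"]:
                raise ImmutableRecordError(f"LFD record {record_id} is locked")
            self.db.execute("DELETE FROM lfd_source WHERE lfd_id = ?", (record_id,))
        if tier == "SFD":
            self.db.execute("DELETE FROM sfd_source WHERE sfd_id = ?", (record_id,))
        self.db.execute(f"DELETE FROM {table} WHERE record_id = ?", (record_id,))
        self.db.commit()

    def lfd_fingerprints(self) -> list[Fingerprint]:
        rows = self.db.execute(
            "SELECT * FROM lfd_record ORDER BY record_id"
        ).fetchall()
        return [self._read_payload(r["file_id"]) for r in rows]

    def lfd_records(self) -> list[str]:
        return [
            r["record_id"]
            for r in self.db.execute(
                "SELECT record_id FROM lfd_record ORDER BY record_id"
            ).fetchall()
        ]

    # -- tracing ------------------------------------------------------------

    def trace(self, record_id: str) -> dict:
        """Full provenance chain of a record, down to wells and images."""
        if record_id.startswith("LFD"):
            row = self.db.execute(
                "SELECT * FROM lfd_record WHERE record_id = ?", (record_id,)
            ).fetchone()
            if row is None:
                raise RecordNotFoundError(f"LFD record {record_id}")
            sources = self.db.execute(
                "SELECT sfd_id FROM lfd_source WHERE lfd_id = ?", (record_id,)
            ).fetchall()
            return {
                "record_id": record_id, "tier": "LFD",
                "sample_id": row["sample_id"], "state": row["state"],
                "sources": [self.trace(s["sfd_id"]) for s in sources],
            }
        if record_id.startswith("SFD"):
            row = self.db.execute(
                "SELECT * FROM sfd_record WHERE record_id = ?", (record_id,)
            ).fetchone()
            if row is None:
                raise RecordNotFoundError(f"SFD record {record_id}")
            sources = self.db.execute(
                "SELECT efd_id FROM sfd_source WHERE sfd_id = ?", (record_id,)
            ).fetchall()
            return {
                "record_id": record_id, "tier": "SFD",
                "sample_id": row["sample_id"], "state": row["state"],
                "sources": [self.trace(s["efd_id"]) for s in sources],
            }
        row = self.db.execute(
            "SELECT * FROM efd_record WHERE record_id = ?", (record_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"record {record_id}")
        fp = self._read_payload(row["file_id"])
        wells = []
        if row["dna_id"]:
            wells = [
                dict(w)
                for w in self.db.execute(
                    "SELECT * FROM pcr_well WHERE dna_id = ?", (row["dna_id"],)
                ).fetchall()
            ]
        return {
            "record_id": record_id, "tier": "EFD",
            "experiment_id": row["experiment_id"],
            "owner": row["owner_experimenter_id"],
            "wells": wells,
            "images": dict(fp.image_refs) if fp.image_refs else {},
            "sources": [],
        }

    @staticmethod
    def trace_leaves(tree: dict) -> list[dict]:
        if not tree["sources"]:
            return [tree]
        out = []
        for child in tree["sources"]:
            out += FingerprintStore.trace_leaves(child)
        return out

    # -- integrity & export -------------------------------------------------

    def check_integrity(self) -> list[tuple]:
        """Foreign-key violations, if any (empty list = consistent)."""
        return self.db.execute("PRAGMA foreign_key_check").fetchall()

    def export_tier(self, tier: str, out_dir: str | Path) -> Path:
        """Dump one tier as a records CSV plus payload JSON files."""
        tier = tier.upper()
        table = {"EFD": "efd_record", "SFD": "sfd_record", "LFD": "lfd_record"}[tier]
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = self.db.execute(f"SELECT * FROM {table} ORDER BY record_id").fetchall()
        import csv

        index = out_dir / f"{tier.lower()}_records.csv"
        with open(index, "w", newline="") as fh:
            writer = None
            for row in rows:
                d = dict(row)
                fp = self._read_payload(d.pop("file_id"))
                payload = out_dir / f"{row['record_id']}.json"
                payload.write_text(json.dumps(fingerprint_to_dict(fp), indent=1))
                d["payload"] = payload.name
                if writer is None:
                    writer = csv.DictWriter(fh, fieldnames=list(d))
                    writer.writeheader()
                writer.writerow(d)
        return index
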