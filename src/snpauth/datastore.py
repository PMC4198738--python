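"""Genotype database: import, recoding, annotation, persistence and merging.

Calls are coded as B-allele dosage — 0 (AA), 1 (AB), 2 (BB) — with NaN for
no-calls. The coding makes B-allele-frequency arithmetic and F1 imputation
closed-form: the expected BAF of a genotype is simply ``code / 2``.

On disk a database is a single portable SQLite file with long-format tables
(``samples``, ``markers``, ``calls``, ``intensities``), so labs can exchange
results as one file and merge them.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Mouse autosomes; the assay is restricted to autosomal markers.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))

#: Tokens treated as a no-call in genotype tables.
NO_CALL_TOKENS = frozenset({"--", "NN", "00", "0", "-", "NA", ""})

NA = np.nan


@dataclass(frozen=True)
class MarkerAnnotation:
    """Position and allele content of one SNP marker.

    ``alleles`` is the ordered (A-allele, B-allele) nucleotide pair; the
    B allele defines the dosage coding. ``position_bp`` is 1-based.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"marker {self.marker_id}: position_bp must be >= 1")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"marker {self.marker_id}: alleles must be distinct")


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one sample (reference panel member or cell line)."""

    sample_id: str
    sample_type: str  # "reference" | "cell_line"
    strain_label: str | None = None
    replicate_group: str | None = None
    outbred: bool = False
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("reference", "cell_line"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.outbred and self.sample_type != "reference":
            raise ValueError(f"sample {self.sample_id}: outbred implies reference type")


class GenotypeMatrix:
    """Sample x marker matrix of B-allele dosages (float32, NaN = no-call)."""

    def __init__(self, samples: Sequence[str], markers: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.float32)
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        finite = calls[np.isfinite(calls)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise ValueError("non-NA calls must be 0, 1 or 2")
        self.samples = list(samples)
        self.markers = list(markers)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._marker_index = {m: i for i, m in enumerate(self.markers)}
        if len(self._sample_index) != len(self.samples):
            raise ValueError("duplicate sample_id in genotype matrix")
        if len(self._marker_index) != len(self.markers):
            raise ValueError("duplicate marker_id in genotype matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self._sample_index[sample_id]]

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self._marker_index[marker_id]]

    def sample_position(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def marker_position(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._marker_index[m] for m in marker_ids]
        return GenotypeMatrix(self.samples, list(marker_ids), self.calls[:, idx])


@dataclass
class Database:
    """In-memory genotype database: call matrix plus marker/sample annotations."""

    genotypes: GenotypeMatrix
    markers: dict[str, MarkerAnnotation]
    samples: dict[str, SampleAnnotation]
    intensities: object | None = None  # IntensityFrame, attached by the intensity module
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for m in self.genotypes.markers:
            if m not in self.markers:
                raise ValueError(f"marker {m!r} has no annotation")
        for s in self.genotypes.samples:
            if s not in self.samples:
                raise ValueError(f"sample {s!r} has no annotation")

    # -- convenience selectors -------------------------------------------------

    def reference_ids(self) -> list[str]:
        return [s for s in self.genotypes.samples if self.samples[s].sample_type == "reference"]

    def cell_line_ids(self) -> list[str]:
        return [s for s in self.genotypes.samples if self.samples[s].sample_type == "cell_line"]

    def outbred_lines(self) -> dict[str, list[str]]:
        """Outbred line label -> sample ids, for lines with a strain label."""
        lines: dict[str, list[str]] = {}
        for s in self.genotypes.samples:
            ann = self.samples[s]
            if ann.outbred and ann.strain_label:
                lines.setdefault(ann.strain_label, []).append(s)
        return lines

    def markers_sorted(self) -> list[str]:
        """Marker ids sorted by (chromosome, position); chromosome order follows
        the numeric mouse convention where possible."""

        def key(m: str):
            ann = self.markers[m]
            chrom = ann.chromosome
            return (0, int(chrom)) if chrom.isdigit() else (1, chrom), ann.position_bp

        return sorted(self.genotypes.markers, key=key)

    def log(self, message: str) -> None:
        self.provenance.append(message)


# ---------------------------------------------------------------------------
# Recoding


def recode_calls(raw_calls: Iterable[str], alleles: tuple[str, str]) -> np.ndarray:
    """Recode two-letter genotype strings to B-allele dosage.

    Heterozygous letter order is ignored ("GT" == "TG"); any call that is not
    composed of the marker's two declared alleles (including explicit no-call
    tokens) becomes NaN.
    """
    a, b = alleles
    out = []
    for raw in raw_calls:
        call = str(raw).strip().upper()
        if len(call) == 2 and set(call) <= {a, b}:
            out.append(float(call.count(b)))
        else:
            out.append(NA)
    return np.asarray(out, dtype=np.float32)


def _annotations_from_tables(
    sample_meta: pd.DataFrame, marker_meta: pd.DataFrame
) -> tuple[dict[str, SampleAnnotation], dict[str, MarkerAnnotation]]:
    samples: dict[str, SampleAnnotation] = {}
    for row in sample_meta.itertuples(index=False):
        d = row._asdict()
        sid = str(d["sample_id"])
        if sid in samples:
            raise ValueError(f"duplicate sample_id {sid!r} in sample metadata")
        samples[sid] = SampleAnnotation(
            sample_id=sid,
            sample_type=str(d.get("sample_type", "reference")),
            strain_label=_opt_str(d.get("strain_label")),
            replicate_group=_opt_str(d.get("replicate_group")),
            outbred=bool(d.get("outbred", False)),
            taxon_label=_opt_str(d.get("taxon_label")),
        )
    markers: dict[str, MarkerAnnotation] = {}
    for row in marker_meta.itertuples(index=False):
        d = row._asdict()
        mid = str(d["marker_id"])
        gc = d.get("gc_fraction")
        markers[mid] = MarkerAnnotation(
            marker_id=mid,
            chromosome=str(d["chromosome"]),
            position_bp=int(d["position_bp"]),
            alleles=(str(d["allele_a"]).upper(), str(d["allele_b"]).upper()),
            gc_fraction=None if gc is None or (isinstance(gc, float) and np.isnan(gc)) else float(gc),
        )
    return samples, markers


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s and s.lower() != "nan" else None


def import_genotype_table(
    path: str | Path,
    format: str,
    sample_meta: pd.DataFrame,
    marker_meta: pd.DataFrame,
) -> Database:
    """Import a genotype call table and recode to B-allele dosage.

    ``format`` is ``"long_tsv"`` (columns sample_id, marker_id, call) or
    ``"ped_map"`` (``path`` names the .ped file; the .map file is expected
    alongside with the same stem). Every marker in the table must be
    annotated, with its alleles declared, in ``marker_meta``.
    """
    path = Path(path)
    sample_anns, marker_anns = _annotations_from_tables(sample_meta, marker_meta)

    if format == "long_tsv":
        table = pd.read_csv(path, sep="\t", dtype=str)
        sample_ids = list(dict.fromkeys(table["sample_id"]))
        marker_ids = list(dict.fromkeys(table["marker_id"]))
        for m in marker_ids:
            if m not in marker_anns:
                raise ValueError(f"marker {m!r} in genotype table has no annotation")
        wide = table.pivot(index="sample_id", columns="marker_id", values="call")
        wide = wide.reindex(index=sample_ids, columns=marker_ids)
        calls = np.full(wide.shape, NA, dtype=np.float32)
        for j, m in enumerate(marker_ids):
            calls[:, j] = recode_calls(wide[m].fillna("--"), marker_anns[m].alleles)
        raw_non_na = (~wide.isna() & ~wide.isin(NO_CALL_TOKENS)).to_numpy()
    elif format == "ped_map":
        map_path = path.with_suffix(".map")
        mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
        marker_ids = list(mp[1])
        rows, sample_ids = [], []
        for line in path.read_text().splitlines():
            fields = line.split()
            if not fields:
                continue
            sid = fields[1]
            if sid in sample_ids:
                raise ValueError(f"duplicate sample_id {sid!r} in PED file")
            sample_ids.append(sid)
            pairs = fields[6:]
            if len(pairs) != 2 * len(marker_ids):
                raise ValueError(f"sample {sid!r}: expected {2 * len(marker_ids)} alleles")
            rows.append(["".join(pairs[2 * i : 2 * i + 2]) for i in range(len(marker_ids))])
        for m in marker_ids:
            if m not in marker_anns:
                raise ValueError(f"marker {m!r} in MAP file has no annotation")
        calls = np.full((len(sample_ids), len(marker_ids)), NA, dtype=np.float32)
        for j, m in enumerate(marker_ids):
            calls[:, j] = recode_calls([r[j] for r in rows], marker_anns[m].alleles)
        raw_non_na = np.array(
            [[r[j] not in ("00", "0-", "-0") for j in range(len(marker_ids))] for r in rows]
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    for s in sample_ids:
        if s not in sample_anns:
            raise ValueError(f"sample {s!r} in genotype table has no annotation")

    n_unparseable = int((raw_non_na & ~np.isfinite(calls)).sum())
    db = Database(
        genotypes=GenotypeMatrix(sample_ids, marker_ids, calls),
        markers={m: marker_anns[m] for m in marker_ids},
        samples={s: sample_anns[s] for s in sample_ids},
    )
    db.log(f"imported {len(sample_ids)} samples x {len(marker_ids)} markers from {path.name}")
    if n_unparseable:
        db.log(f"{n_unparseable} unparseable calls recoded to NA")
    return db


# ---------------------------------------------------------------------------
# Merging


def merge_databases(a: Database, b: Database, marker_policy: str = "intersection") -> Database:
    """Union of samples over a shared marker set.

    Overlapping marker ids must carry identical annotations. A sample id
    present in both inputs with different calls on the shared markers is kept
    twice, the second copy renamed with a numeric suffix; identical duplicates
    collapse to one copy.
    """
    if marker_policy not in ("intersection", "union"):
        raise ValueError(f"unknown marker policy {marker_policy!r}")

    for m in set(a.markers) & set(b.markers):
        ma, mb = a.markers[m], b.markers[m]
        if (ma.chromosome, ma.position_bp, ma.alleles) != (mb.chromosome, mb.position_bp, mb.alleles):
            raise ValueError(f"marker {m!r} has conflicting annotations")

    if marker_policy == "intersection":
        markers = [m for m in a.genotypes.markers if m in b.markers]
    else:
        markers = list(a.genotypes.markers) + [m for m in b.genotypes.markers if m not in a.markers]

    log: list[str] = list(a.provenance) + list(b.provenance)
    n = len(markers)

    def calls_for(db: Database, sample: str) -> np.ndarray:
        out = np.full(n, NA, dtype=np.float32)
        row = db.genotypes.row(sample)
        for j, m in enumerate(markers):
            if m in db.markers:
                out[j] = row[db.genotypes.marker_position(m)]
        return out

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    anns: dict[str, SampleAnnotation] = {}
    for s in a.genotypes.samples:
        sample_ids.append(s)
        rows.append(calls_for(a, s))
        anns[s] = a.samples[s]
    for s in b.genotypes.samples:
        row = calls_for(b, s)
        if s in anns:
            prev = rows[sample_ids.index(s)]
            both = np.isfinite(prev) & np.isfinite(row)
            if np.array_equal(prev[both], row[both]):
                log.append(f"duplicate sample {s!r} with identical calls collapsed")
                continue
            new_id, k = s, 2
            while new_id in anns:
                new_id = f"{s}_{k}"
                k += 1
            log.append(f"conflicting duplicate sample {s!r} renamed to {new_id!r}")
            anns[new_id] = replace(b.samples[s], sample_id=new_id)
            sample_ids.append(new_id)
            rows.append(row)
        else:
            anns[s] = b.samples[s]
            sample_ids.append(s)
            rows.append(row)

    marker_anns = {m: (a.markers.get(m) or b.markers[m]) for m in markers}
    merged = Database(
        genotypes=GenotypeMatrix(sample_ids, markers, np.vstack(rows) if rows else np.empty((0, n))),
        markers=marker_anns,
        samples=anns,
        provenance=log,
    )
    merged.log(f"merged databases: {len(sample_ids)} samples, {n} markers ({marker_policy})")
    return merged


# ---------------------------------------------------------------------------
# Persistence (single-file SQLite store) and TSV export

_SCHEMA = """
CREATE TABLE samples (
    sample_id TEXT PRIMARY KEY, sample_type TEXT NOT NULL, strain_label TEXT,
    replicate_group TEXT, outbred INTEGER NOT NULL, taxon_label TEXT, ordinal INTEGER
);
CREATE TABLE markers (
    marker_id TEXT PRIMARY KEY, chromosome TEXT NOT NULL, position_bp INTEGER NOT NULL,
    allele_a TEXT NOT NULL, allele_b TEXT NOT NULL, gc_fraction REAL, ordinal INTEGER
);
CREATE TABLE calls (sample_id TEXT, marker_id TEXT, code REAL);
CREATE TABLE intensities (sample_id TEXT, marker_id TEXT, x REAL, y REAL, baf REAL, lrr REAL);
CREATE TABLE provenance (line TEXT);
"""


def save_database(db: Database, path: str | Path) -> None:
    """Write the database to a single-file SQLite store (long-format tables)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO samples VALUES (?,?,?,?,?,?,?)",
            [
                (s.sample_id, s.sample_type, s.strain_label, s.replicate_group,
                 int(s.outbred), s.taxon_label, i)
                for i, s in enumerate(db.samples[sid] for sid in db.genotypes.samples)
            ],
        )
        con.executemany(
            "INSERT INTO markers VALUES (?,?,?,?,?,?,?)",
            [
                (m.marker_id, m.chromosome, m.position_bp, m.alleles[0], m.alleles[1],
                 m.gc_fraction, i)
                for i, m in enumerate(db.markers[mid] for mid in db.genotypes.markers)
            ],
        )
        calls = db.genotypes.calls
        records = [
            (db.genotypes.samples[i], db.genotypes.markers[j], float(calls[i, j]))
            for i in range(calls.shape[0])
            for j in range(calls.shape[1])
            if np.isfinite(calls[i, j])
        ]
        con.executemany("INSERT INTO calls VALUES (?,?,?)", records)
        frame = db.intensities
        if frame is not None:
            con.executemany(
                "INSERT INTO intensities VALUES (?,?,?,?,?,?)", frame.to_records()
            )
        con.executemany("INSERT INTO provenance VALUES (?)", [(l,) for l in db.provenance])
        con.commit()
    finally:
        con.close()


def load_database(path: str | Path) -> Database:
    """Load a database written by :func:`save_database`."""
    from .intensity import IntensityFrame  # local import to avoid a cycle

    con = sqlite3.connect(path)
    try:
        samples = {}
        order_s = []
        for sid, stype, strain, rep, outbred, taxon, _ in con.execute(
            "SELECT * FROM samples ORDER BY ordinal"
        ):
            samples[sid] = SampleAnnotation(sid, stype, strain, rep, bool(outbred), taxon)
            order_s.append(sid)
        markers = {}
        order_m = []
        for mid, chrom, pos, aa, ab, gc, _ in con.execute(
            "SELECT * FROM markers ORDER BY ordinal"
        ):
            markers[mid] = MarkerAnnotation(mid, chrom, pos, (aa, ab), gc)
            order_m.append(mid)
        s_idx = {s: i for i, s in enumerate(order_s)}
        m_idx = {m: i for i, m in enumerate(order_m)}
        calls = np.full((len(order_s), len(order_m)), NA, dtype=np.float32)
        for sid, mid, code in con.execute("SELECT * FROM calls"):
            calls[s_idx[sid], m_idx[mid]] = code
        rows = list(con.execute("SELECT * FROM intensities"))
        frame = IntensityFrame.from_records(rows, order_s, order_m) if rows else None
        prov = [line for (line,) in con.execute("SELECT line FROM provenance")]
    finally:
        con.close()
    return Database(
        genotypes=GenotypeMatrix(order_s, order_m, calls),
        markers=markers,
        samples=samples,
        intensities=frame,
        provenance=prov,
    )


def write_long_tsv(db: Database, path: str | Path) -> None:
    """Export calls as a long-format TSV (sample_id, marker_id, call letters)."""
    rows = []
    for i, s in enumerate(db.genotypes.samples):
        for j, m in enumerate(db.genotypes.markers):
            code = db.genotypes.calls[i, j]
            a, b = db.markers[m].alleles
            if not np.isfinite(code):
                call = "--"
            else:
                call = {0: a + a, 1: a + b, 2: b + b}[int(code)]
            rows.append((s, m, call))
    pd.DataFrame(rows, columns=["sample_id", "marker_id", "call"]).to_csv(
        path, sep="\t", index=False
    )


def sample_table(db: Database) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id, "sample_type": a.sample_type,
                "strain_label": a.strain_label, "replicate_group": a.replicate_group,
                "outbred": a.outbred, "taxon_label": a.taxon_label,
            }
            for a in (db.samples[s] for s in db.genotypes.samples)
        ]
    )


def marker_table(db: Database) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_id": m.marker_id, "chromosome": m.chromosome,
                "position_bp": m.position_bp, "allele_a": m.alleles[0],
                "allele_b": m.alleles[1], "gc_fraction": m.gc_fraction,
            }
            for m in (db.markers[mid] for mid in db.genotypes.markers)
        ]
    )
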