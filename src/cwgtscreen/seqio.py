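"""Readers and writers for the external formats the pipeline touches.

Everything downstream — feature annotation, homolog culling, construct
design, hit calling — consumes the record types defined here.  The module
also ships transcriptions of the published screening tables (the 46-entry
protein library, the 19 test-library hits and the 17 crop-library hits)
as packaged TSV fixtures, loadable without network access.

Dialects are deliberately narrow: FASTA with ``>`` headers and arbitrary
line wrap; header-bearing TSV/CSV for tabular data (delimiter
auto-detection is limited to tab and comma); all text is UTF-8.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "STANDARD_RESIDUES",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
    "ProteinRecord",
    "CodingRecord",
    "CodonUsageTable",
    "PeakRecord",
    "HomologHit",
    "PaperTables",
    "Table2Hit",
    "Table3Hit",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "hits_from_outfmt6",
    "read_codon_usage",
    "read_peak_table",
    "write_peak_table",
    "load_paper_tables",
]

#: The 20 standard one-letter amino-acid codes plus X (unknown).
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_STANDARD_TABLE = _CodonTable.unambiguous_dna_by_id[1]

#: The 61 sense codons of the standard genetic code.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.forward_table))

#: Mapping amino acid -> tuple of its synonymous sense codons.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = _STANDARD_TABLE.forward_table[_codon]
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: Reverse lookup codon -> amino acid (sense codons only).
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with organism/family metadata.

    ``family`` carries a CAZy or DUF label where known, ``gene_identifier``
    the locus identifier (e.g. ``At3g02230``); both may be empty.
    """

    id: str
    residues: str
    organism: str = ""
    family: str = ""
    gene_identifier: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingRecord:
    """A coding sequence stored as an ordered list of nucleotide triplets."""

    id: str
    codons: tuple[str, ...]

    @classmethod
    def from_sequence(cls, id: str, nt: str) -> "CodingRecord":
        nt = nt.upper().replace("U", "T")
        if len(nt) % 3 != 0:
            raise ValueError(
                f"coding sequence {id!r}: length {len(nt)} not divisible by 3"
            )
        bad = set(nt) - set("ACGT")
        if bad:
            raise ValueError(
                f"coding sequence {id!r}: ambiguity codes not allowed: {sorted(bad)}"
            )
        codons = tuple(nt[i : i + 3] for i in range(0, len(nt), 3))
        return cls(id=id, codons=codons)

    def __len__(self) -> int:
        return len(self.codons)


class CodonUsageTable:
    """Relative synonymous codon frequencies for one organism.

    Each of the 61 sense codons maps to its fraction *within its
    synonymous family* (so the frequencies of the codons encoding one
    amino acid sum to 1).  Input values may be raw counts or per-1000
    usage; they are renormalized per family on construction, which is a
    no-op for already-normalized tables.
    """

    def __init__(self, values: dict[str, float]):
        cleaned: dict[str, float] = {}
        for codon, value in values.items():
            codon = codon.upper().replace("U", "T")
            if value < 0:
                raise ValueError(f"codon {codon}: negative frequency {value}")
            cleaned[codon] = float(value)
        missing = [c for c in SENSE_CODONS if c not in cleaned]
        if missing:
            raise ValueError(f"missing sense codons: {', '.join(missing)}")
        self.frequencies: dict[str, float] = {}
        for codons in SYNONYMOUS_FAMILIES.values():
            total = sum(cleaned[c] for c in codons)
            for c in codons:
                # an all-zero family degenerates to the uniform distribution
                self.frequencies[c] = (
                    cleaned[c] / total if total > 0 else 1.0 / len(codons)
                )

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon.upper().replace("U", "T")]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonUsageTable):
            return NotImplemented
        return self.frequencies == other.frequencies


@dataclass(frozen=True)
class PeakRecord:
    """One capillary-electrophoresis peak for one screened sample."""

    sample_id: str
    observed_mw: float  # kDa
    concentration: float  # ug/mL
    purity: float  # percent

    def __post_init__(self) -> None:
        if self.observed_mw <= 0:
            raise ValueError(f"sample {self.sample_id}: observed_mw must be > 0")
        if self.concentration < 0:
            raise ValueError(f"sample {self.sample_id}: negative concentration")
        if not 0 <= self.purity <= 100:
            raise ValueError(
                f"sample {self.sample_id}: purity {self.purity} outside [0, 100]"
            )


@dataclass
class HomologHit:
    """One row of a homology search export: query id, subject sequence,
    optional percent identity (as a fraction; computed later if absent)."""

    query_id: str
    subject: ProteinRecord
    identity: Optional[float] = None
    length_ratio: Optional[float] = None  # subject/query length, set at cull time

    def __post_init__(self) -> None:
        if self.identity is not None and not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject.id}: identity "
                f"{self.identity} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects, order preserved.

    The header token before the first whitespace becomes the id; the
    remainder is parsed opportunistically for ``key=value`` pairs
    (``organism=...``, ``family=...``, ``gene=...``).  Line-wrapped
    sequences are concatenated.  Duplicate ids, illegal residues and
    empty files are errors.
    """
    text = Path(path).read_text(encoding="utf-8")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        rid = tokens[0]
        meta = {}
        if len(tokens) > 1:
            for tok in tokens[1].split():
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    meta[key.lower()] = val
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        records.append(
            ProteinRecord(
                id=rid,
                residues="".join(chunks).upper(),
                organism=meta.get("organism", "").replace("_", " "),
                family=meta.get("family", ""),
                gene_identifier=meta.get("gene", ""),
            )
        )

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            raise ValueError("comment lines (';') are not supported")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise ValueError("empty FASTA header")
            chunks = []
        else:
            if header is None:
                raise ValueError("sequence data before first header")
            chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; metadata goes into key=value tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            extras = []
            if rec.organism:
                extras.append(f"organism={rec.organism.replace(' ', '_')}")
            if rec.family:
                extras.append(f"family={rec.family}")
            if rec.gene_identifier:
                extras.append(f"gene={rec.gene_identifier}")
            suffix = (" " + " ".join(extras)) if extras else ""
            fh.write(f">{rec.id}{suffix}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str:
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_rows(path) -> tuple[list[str], list[dict[str, str]]]:
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty table {path}")
    delim = _sniff_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    fields = [f.strip() for f in reader.fieldnames or []]
    rows = [
        {k.strip(): (v or "").strip() for k, v in row.items() if k is not None}
        for row in reader
    ]
    return fields, rows


def read_hit_table(path) -> list[HomologHit]:
    """Read a header-bearing TSV of homology hits.

    Mandatory columns: ``query_id``, ``subject_id``, ``subject_seq``;
    optional ``identity_pct`` (percent, stored as a fraction).
    """
    fields, rows = _read_rows(path)
    for col in ("query_id", "subject_id", "subject_seq"):
        if col not in fields:
            raise ValueError(f"missing column {col}")
    hits: list[HomologHit] = []
    for row in rows:
        identity: Optional[float] = None
        if "identity_pct" in fields and row.get("identity_pct", "") != "":
            pct = float(row["identity_pct"])
            if not 0.0 <= pct <= 100.0:
                raise ValueError(
                    f"identity_pct {pct} outside [0, 100] for subject "
                    f"{row['subject_id']!r}"
                )
            identity = pct / 100.0
        hits.append(
            HomologHit(
                query_id=row["query_id"],
                subject=ProteinRecord(
                    id=row["subject_id"], residues=row["subject_seq"].upper()
                ),
                identity=identity,
            )
        )
    return hits


def hits_from_outfmt6(path, subject_fasta) -> list[HomologHit]:
    """Convert BLAST ``-outfmt "6 qseqid sseqid pident"`` plus a subject
    FASTA into :class:`HomologHit` rows (plumbing for the culling stage)."""
    subjects = {rec.id: rec for rec in read_fasta(subject_fasta)}
    hits: list[HomologHit] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected qseqid, sseqid, pident")
        qid, sid, pident = parts[0], parts[1], float(parts[2])
        if sid not in subjects:
            raise ValueError(f"line {lineno}: subject {sid!r} not in FASTA")
        hits.append(
            HomologHit(query_id=qid, subject=subjects[sid], identity=pident / 100.0)
        )
    return hits


def read_codon_usage(path) -> CodonUsageTable:
    """Read a tab-delimited ``codon<TAB>frequency`` table.

    Accepts counts, per-1000 usage or fractions (renormalized per
    synonymous family either way); RNA codons (U) are transliterated.
    A header row is optional.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected codon and frequency")
        codon = parts[0].strip().upper().replace("U", "T")
        if lineno == 1 and not set(codon) <= set("ACGT"):
            continue  # header row
        try:
            value = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable frequency {parts[1]!r}") from exc
        if codon in STOP_CODONS:
            continue
        values[codon] = value
    return CodonUsageTable(values)


def read_peak_table(path) -> list[PeakRecord]:
    """Read a delimited peak table with columns ``sample_id``, ``mw_kda``,
    ``conc_ug_ml``, ``purity_pct``; several rows (peaks) per sample are
    allowed.  A header-only file yields an empty list."""
    fields, rows = _read_rows(path)
    for col in ("sample_id", "mw_kda", "conc_ug_ml", "purity_pct"):
        if col not in fields:
            raise ValueError(f"missing column {col}")
    peaks: list[PeakRecord] = []
    for idx, row in enumerate(rows, start=1):
        try:
            mw = float(row["mw_kda"])
            conc = float(row["conc_ug_ml"])
            purity = float(row["purity_pct"])
        except ValueError as exc:
            raise ValueError(f"row {idx}: unparseable number ({exc})") from exc
        try:
            peaks.append(
                PeakRecord(
                    sample_id=row["sample_id"],
                    observed_mw=mw,
                    concentration=conc,
                    purity=purity,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return peaks


def write_peak_table(peaks: Iterable[PeakRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "mw_kda", "conc_ug_ml", "purity_pct"])
        for p in peaks:
            writer.writerow(
                [p.sample_id, f"{p.observed_mw:.3f}", f"{p.concentration:.3f}",
                 f"{p.purity:.3f}"]
            )


# ---------------------------------------------------------------------------
# Packaged screening-table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table2Hit:
    """A mass-spec-confirmed hit from the 684-sample test-library screen."""

    protein: str
    construct: str
    vector: str
    chaperones: str
    yield_ug_ml: float


@dataclass(frozen=True)
class Table3Hit:
    """A mass-spec-confirmed hit from the 138-sample crop-library screen."""

    id: str
    protein: str
    well: str
    construct: str
    species: str
    yield_ug_ml: float


@dataclass(frozen=True)
class PaperTables:
    library: tuple[ProteinRecord, ...]  # 46 screened proteins (metadata only)
    test_hits: tuple[Table2Hit, ...]  # 19 confirmed test-library hits
    crop_hits: tuple[Table3Hit, ...]  # 17 confirmed crop-library hits


def _data_text(name: str) -> str:
    return (resources.files("cwgtscreen") / "data" / name).read_text(encoding="utf-8")


def load_paper_tables() -> PaperTables:
    """Load the packaged transcriptions of the published screening tables.

    The protein library entries carry metadata only (id, gene identifier,
    family, organism); sequences were never printed and must be fetched
    separately by gene identifier when needed.  A placeholder residue
    ``X`` keeps the records constructible.
    """
    lib_reader = csv.DictReader(io.StringIO(_data_text("table1.tsv")), delimiter="\t")
    library = []
    for i, row in enumerate(lib_reader, start=1):
        library.append(
            ProteinRecord(
                id=f"{row['protein']}|{row['gene_identifier']}",
                residues="X",  # sequence not part of the transcription
                organism=row["organism"],
                family=row["family"],
                gene_identifier=row["gene_identifier"],
            )
        )
    t2_reader = csv.DictReader(io.StringIO(_data_text("table2.tsv")), delimiter="\t")
    test_hits = tuple(
        Table2Hit(
            protein=row["protein"],
            construct=row["construct"],
            vector=row["vector"],
            chaperones=row["chaperones"],
            yield_ug_ml=float(row["yield_ug_ml"]),
        )
        for row in t2_reader
    )
    t3_reader = csv.DictReader(io.StringIO(_data_text("table3.tsv")), delimiter="\t")
    crop_hits = tuple(
        Table3Hit(
            id=row["id"],
            protein=row["protein"],
            well=row["well"],
            construct=row["construct"],
            species=row["species"],
            yield_ug_ml=float(row["yield_ug_ml"]),
        )
        for row in t3_reader
    )
    return PaperTables(
        library=tuple(library), test_hits=test_hits, crop_hits=crop_hits
    )
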