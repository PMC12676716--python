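"""Sequence and table I/O, taxonomy-dialect parsing, and IUPAC utilities.

Reference 16S / plastid sequences arrive as FASTA with taxonomy embedded in
the description line; the two databases relevant here use different header
dialects (PhytoREF pipes fields with ``|``, SILVA appends a
semicolon-separated lineage after the accession).  ASV count data arrive as
three tab-separated tables: counts (ASV x sample), a taxonomy map, and
per-sample metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

# Canonical rank order used for every ranked lineage in the package.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

# IUPAC nucleotide codes -> set of unambiguous bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class TableFormatError(ValueError):
    """Raised when the ASV count / taxonomy / metadata tables disagree."""


def iupac_match(pattern_base: str, target_base: str) -> bool:
    """True if ``target_base`` is within the expansion of ``pattern_base``.

    A target-side ``N`` (unknown base in the database sequence) matches only
    an ``N`` pattern: an unknown base never counts as a primer or spacer
    match, which keeps coverage estimates conservative on low-quality
    database entries.
    """
    try:
        expansion = IUPAC_CODES[pattern_base]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {pattern_base!r}") from None
    if target_base == "N":
        return pattern_base == "N"
    if target_base not in IUPAC_CODES:
        raise ValueError(f"unknown target base {target_base!r}")
    return target_base in expansion


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered lineage from domain to species.

    ``ranks`` always carries the full fixed rank list for the ranked
    dialects (``phytoref``, ``silva``); unannotated levels are empty strings
    and are preserved, never dropped.  The ``generic`` dialect stores one
    unranked name.
    """

    ranks: tuple[tuple[str, str], ...]
    dialect: str = "generic"

    def name_at(self, rank: str) -> str:
        for r, name in self.ranks:
            if r == rank:
                return name
        return ""

    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def contains(self, term: str) -> bool:
        """Case-insensitive substring match against any taxon name."""
        t = term.lower()
        return any(t in name.lower() for name in self.names())

    @classmethod
    def empty(cls, dialect: str = "generic") -> "TaxonomyLineage":
        return cls(tuple((r, "") for r in RANKS), dialect=dialect)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return ";".join(self.names()).rstrip(";")


@dataclass
class SequenceRecord:
    """One reference sequence with its parsed taxonomy lineage."""

    id: str
    description: str
    seq: str
    lineage: TaxonomyLineage | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def detect_dialect(description: str) -> str:
    """Guess the taxonomy header dialect from its shape.

    PhytoREF joins fields with ``|``; SILVA appends a semicolon-separated
    lineage; anything else is treated as a single unranked name.
    """
    if "|" in description:
        return "phytoref"
    if ";" in description:
        return "silva"
    return "generic"


def parse_taxonomy_header(description: str, dialect: str | None = None) -> TaxonomyLineage:
    """Parse a FASTA description line into a :class:`TaxonomyLineage`.

    Best-effort: an unparseable header yields an all-empty lineage with a
    logged warning rather than an exception, so a single odd database entry
    cannot abort a screen.
    """
    if dialect is None:
        dialect = detect_dialect(description)
    if dialect not in {"phytoref", "silva", "generic"}:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")

    text = description.strip()
    if dialect == "generic":
        ranks = [("name", text)]
        return TaxonomyLineage(tuple(ranks), dialect="generic")

    if dialect == "phytoref":
        # accession|name|lineage-fields... -> lineage is everything after
        # the first field that looks like a semicolon list, else the pipe
        # fields themselves are the lineage.
        fields = [f.strip() for f in text.split("|")]
        semicolon = [f for f in fields if ";" in f]
        parts = (
            [p.strip() for p in semicolon[0].split(";")]
            if semicolon
            else fields[1:]
        )
    else:  # silva: "ACC.start.stop Domain;Phylum;...;Genus" or bare lineage
        _, _, tail = text.partition(" ")
        if not tail and ";" in text:
            tail = text
        parts = [p.strip() for p in tail.split(";")] if tail else []

    if not parts:
        logger.warning("unparseable taxonomy header: %r", description)
        return TaxonomyLineage.empty(dialect=dialect)

    names = (parts + [""] * len(RANKS))[: len(RANKS)]
    return TaxonomyLineage(
        tuple(zip(RANKS, names)), dialect=dialect
    )


def _normalize_seq(raw: str) -> str:
    # SILVA distributes rRNA in the RNA alphabet; fold U->T on load.
    return raw.upper().replace("U", "T")


def read_fasta(
    path: str | Path, dialect: str | None = None, parse_lineage: bool = True
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T.  Records keep file
    order.  A sequence line appearing before any header is a structural
    error and is reported with its line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first "
                    f"'>' header"
                )
            break

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {bio.id!r}")
        seen.add(bio.id)
        lineage = (
            parse_taxonomy_header(bio.description, dialect)
            if parse_lineage
            else None
        )
        records.append(
            SequenceRecord(
                id=bio.id,
                description=bio.description,
                seq=_normalize_seq(str(bio.seq)),
                lineage=lineage,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and descriptions."""
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library of one isolated cell.

    Paired libraries of the same physical cell share ``cell_id`` and differ
    only in ``treatment`` (``SC-seq`` control vs ``SCHoCO-seq`` Cas9
    digest).
    """

    sample_id: str
    cell_id: str
    strain: str = "other"
    condition: str = "other"
    prep: str = "SC-PCR"
    treatment: str = "SC-seq"


@dataclass
class AsvTable:
    """An ASV x sample count matrix with taxonomy and sample metadata.

    ``counts`` holds raw non-negative integer read counts; scaled or
    transformed values live in :class:`schoco.pipeline.NormalizedTable` so
    that integer preconditions of downstream steps (SRS in particular) stay
    checkable.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyLineage] = field(default_factory=dict)
    samples: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise TableFormatError("negative counts present")
        if not all(
            pd.api.types.is_integer_dtype(dt) for dt in c.dtypes
        ):
            raise TableFormatError("counts must be integers")
        missing_tax = [a for a in c.index if a not in self.taxonomy]
        for a in missing_tax:
            self.taxonomy[a] = TaxonomyLineage.empty()
        missing_meta = [s for s in c.columns if s not in self.samples]
        if missing_meta:
            raise TableFormatError(
                f"samples without metadata: {missing_meta}"
            )
        pairs = [(m.cell_id, m.treatment) for m in self.samples.values()]
        if len(pairs) != len(set(pairs)):
            raise TableFormatError(
                "(cell_id, treatment) pairs must be unique"
            )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return AsvTable(
            counts=self.counts[keep].copy(),
            taxonomy=dict(self.taxonomy),
            samples={s: self.samples[s] for s in keep},
        )

    def subset_asvs(self, asv_ids: Sequence[str]) -> "AsvTable":
        keep = [a for a in self.asv_ids if a in set(asv_ids)]
        return AsvTable(
            counts=self.counts.loc[keep].copy(),
            taxonomy={a: self.taxonomy[a] for a in keep},
            samples=dict(self.samples),
        )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_asv_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    dialect: str | None = None,
) -> AsvTable:
    """Assemble an :class:`AsvTable` from three TSV files.

    ``counts``: ASV rows x sample columns.  ``taxonomy``: ASV id ->
    lineage string (column ``taxonomy``).  ``metadata``: sample id ->
    cell_id / strain / condition / prep / treatment columns.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    try:
        counts = raw.astype("int64")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(
            f"{counts_path}: non-integer count value ({exc})"
        ) from None
    if not (counts.values == raw.values).all():
        raise TableFormatError(f"{counts_path}: non-integer count value")
    if (counts.values < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)].tolist()
        raise TableFormatError(
            f"{counts_path}: negative counts in ASVs {bad}"
        )

    tax_df = _read_tsv(taxonomy_path)
    tax_col = "taxonomy" if "taxonomy" in tax_df.columns else tax_df.columns[0]
    taxonomy = {
        asv: parse_taxonomy_header(str(s) if pd.notna(s) else "", dialect)
        for asv, s in tax_df[tax_col].items()
    }

    meta_df = _read_tsv(metadata_path)
    missing = [s for s in counts.columns if s not in meta_df.index]
    if missing:
        raise TableFormatError(
            f"samples in counts absent from metadata: {missing}"
        )
    samples = {}
    for sid in counts.columns:
        row = meta_df.loc[sid]
        samples[sid] = SampleMeta(
            sample_id=sid,
            cell_id=str(row.get("cell_id", sid)),
            strain=str(row.get("strain", "other")),
            condition=str(row.get("condition", "other")),
            prep=str(row.get("prep", "SC-PCR")),
            treatment=str(row.get("treatment", "SC-seq")),
        )

    unmatched_rows = [a for a in counts.index if a not in taxonomy]
    if unmatched_rows:
        logger.warning(
            "%d ASVs missing from taxonomy table; empty lineage assigned",
            len(unmatched_rows),
        )
    return AsvTable(counts=counts, taxonomy=taxonomy, samples=samples)


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text one-id-per-line exclusion list (``#`` comments)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
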