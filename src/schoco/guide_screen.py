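"""Cas9 spacer screening against 16S reference databases.

A single guide RNA directs Cas9 to a 20-nt protospacer that must sit
immediately 5' of an NGG PAM (SpCas9).  This module enumerates candidate
spacers inside a host chloroplast amplicon, measures how conserved a chosen
spacer is across a target clade, screens a prokaryote database for
off-target sites with a mismatch tolerance, matches degenerate PCR primers,
and computes the joint "would the whole nested workflow amplify and cut
this sequence" coverage.  Mismatches are counted over the 20 spacer
positions only; the PAM is gated separately and never contributes to the
mismatch count.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from schoco.formats import (
    IUPAC_CODES,
    SequenceRecord,
    reverse_complement,
    write_fasta,
)

# Printed oligos of the sgRNA synthesis design.  The specific oligo carries
# the T7 promoter, an initiating G, the 20-nt spacer, and the start of the
# tracrRNA scaffold; the universal oligo is the remainder of the scaffold in
# antisense orientation.
T7_PROMOTER = "TAATACGACTCACTATAG"
SCAFFOLD_PREFIX = "GTTTTAGAGCTAGAAATAG"
UNIVERSAL_OLIGO = (
    "AAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTTAACTTGCTATTTCT"
)
SPECIFIC_OLIGO = (
    "TAATACGACTCACTATAGGAAGTCAACTGTTAAATCTTGGTTTTAGAGCTAGAAATAG"
)
SELECTED_SPACER = "AAGTCAACTGTTAAATCTTG"

#: Outer (V1-V9) and inner (V4) amplification primers.
PRIMERS: dict[str, str] = {
    "27F": "AGAGTTTGATYMTGGCTCAG",
    "1492R": "TACGGYTACCTTGTTACGACTT",
    "515F": "GTGCCAGCMGCCGCGGTAA",
    "806R": "GGACTACHVGGGTWTCTAAT",
}

SPACER_LEN = 20
PAM_LEN = 3


class SpacerError(ValueError):
    """Raised for malformed spacers or anchor failures."""


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt spacer with its observed PAM context.

    ``start`` is the 0-based plus-strand coordinate where the 23-nt
    protospacer+PAM block begins (for plus-strand candidates this equals the
    spacer start; for minus-strand candidates the block reads
    PAM-complement then spacer-complement along the plus strand).
    """

    spacer: str
    pam: str
    source_id: str
    start: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise SpacerError(f"spacer must be {SPACER_LEN} nt")
        if not (len(self.pam) == PAM_LEN and self.pam.endswith("GG")):
            raise SpacerError(f"PAM {self.pam!r} is not NGG")
        if self.strand not in "+-":
            raise SpacerError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MatchHit:
    """One protospacer match: (sequence, position, strand, mismatches).

    ``position`` is the 0-based start of the 20-nt protospacer along the
    hit strand's own 5'->3' orientation (i.e. on the reverse-complemented
    sequence for minus-strand hits).
    """

    seq_id: str
    position: int
    strand: str
    mismatches: int
    pam_ok: bool


@dataclass
class CoverageReport:
    """How many database sequences carry at least one qualifying site."""

    n_db: int
    n_hit: int
    per_taxon: dict[str, tuple[int, int]]  # taxon -> (n_db, n_hit)
    miss_ids: list[str]
    rank: str = "family"

    @property
    def fraction(self) -> float:
        return self.n_hit / self.n_db if self.n_db else 0.0

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "taxon": taxon,
                "rank": self.rank,
                "n_db": nd,
                "n_hit": nh,
                "fraction": nh / nd if nd else 0.0,
            }
            for taxon, (nd, nh) in sorted(self.per_taxon.items())
        ]
        rows.append(
            {
                "taxon": "__total__",
                "rank": self.rank,
                "n_db": self.n_db,
                "n_hit": self.n_hit,
                "fraction": self.fraction,
            }
        )
        return rows


@dataclass
class OfftargetReport:
    """Partition of spacer matches in a (non-target) database.

    ``exact_hits`` and ``near_hits[k]`` hold hits on sequences whose
    lineage did NOT match any exclusion term; hits on excluded lineages
    (e.g. organellar entries in a prokaryote database) are set aside in
    ``excluded_hits``.  ``fraction_flagged`` is the fraction of database
    sequences with at least one non-excluded hit.
    """

    n_db: int
    max_mm: int
    exact_hits: list[MatchHit] = field(default_factory=list)
    near_hits: dict[int, list[MatchHit]] = field(default_factory=dict)
    excluded_hits: list[MatchHit] = field(default_factory=list)
    flagged_ids: list[str] = field(default_factory=list)

    @property
    def fraction_flagged(self) -> float:
        return len(self.flagged_ids) / self.n_db if self.n_db else 0.0

    def counts_by_mismatch(self) -> dict[int, int]:
        out = {0: len(self.exact_hits)}
        for k in range(1, self.max_mm + 1):
            out[k] = len(self.near_hits.get(k, []))
        return out


@dataclass(frozen=True)
class SgrnaTemplate:
    """Fusion of the specific and universal oligos into one dsDNA template."""

    seq: str
    overlap: int

    @property
    def length(self) -> int:
        return len(self.seq)


def extract_spacer(specific_oligo: str) -> str:
    """Recover the 20-nt spacer from a T7 sgRNA specific oligo.

    The oligo layout is ``T7 promoter + initiating G + spacer + scaffold
    prefix``.  The initiating G belongs to transcription start, not to the
    spacer, so a 21-nt insert loses its leading G; a 20-nt insert is taken
    verbatim (designs whose spacer already starts with G fold the
    initiating G into the spacer).
    """
    oligo = specific_oligo.upper().replace("U", "T")
    p = oligo.find(T7_PROMOTER)
    if p < 0:
        raise SpacerError("T7 promoter anchor not found in specific oligo")
    s = oligo.find(SCAFFOLD_PREFIX, p + len(T7_PROMOTER))
    if s < 0:
        raise SpacerError("scaffold anchor not found in specific oligo")
    insert = oligo[p + len(T7_PROMOTER): s]
    if len(insert) == SPACER_LEN + 1 and insert.startswith("G"):
        return insert[1:]
    if len(insert) == SPACER_LEN:
        return insert
    raise SpacerError(
        f"insert between promoter and scaffold is {len(insert)} nt; "
        f"expected {SPACER_LEN} or {SPACER_LEN + 1}"
    )


def enumerate_candidates(
    record: SequenceRecord,
    window_start: int = 0,
    window_end: int | None = None,
) -> list[GuideCandidate]:
    """All 20-mers immediately 5' of an NGG, on either strand, in a window.

    Candidates whose spacer contains an ambiguous base are skipped.  Output
    is sorted by plus-strand block position, then strand.
    """
    seq = record.seq
    if window_end is None:
        window_end = len(seq)
    if not (0 <= window_start <= window_end <= len(seq)):
        raise ValueError(
            f"window [{window_start}, {window_end}) outside sequence of "
            f"length {len(seq)}"
        )
    out: list[GuideCandidate] = []
    block = SPACER_LEN + PAM_LEN
    for p in range(window_start, window_end - block + 1):
        # plus strand: spacer at [p, p+20), PAM at [p+20, p+23)
        pam = seq[p + SPACER_LEN: p + block]
        spacer = seq[p: p + SPACER_LEN]
        if pam[1:] == "GG" and set(spacer) <= set("ACGT"):
            out.append(
                GuideCandidate(spacer, pam, record.id, p, "+")
            )
        # minus strand: plus-strand block reads CCN + revcomp(spacer)
        if seq[p: p + 2] == "CC":
            spacer_m = reverse_complement(seq[p + PAM_LEN: p + block])
            pam_m = reverse_complement(seq[p: p + PAM_LEN])
            if set(spacer_m) <= set("ACGT"):
                out.append(
                    GuideCandidate(spacer_m, pam_m, record.id, p, "-")
                )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


_BASE_ORD = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    # non-ACGT bases (incl. N and ambiguity codes) encode to 255 and can
    # never equal a spacer base: an unknown base is never a match.
    arr = np.full(len(seq), 255, dtype=np.uint8)
    for base, code in _BASE_ORD.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def _scan_one_strand(
    spacer_arr: np.ndarray, seq: str, max_mm: int, require_pam: bool
) -> list[tuple[int, int]]:
    """(position, mismatches) of qualifying sites on the given sequence."""
    n = len(seq)
    if n < SPACER_LEN + (PAM_LEN if require_pam else 0):
        return []
    enc = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(enc, SPACER_LEN)
    mm = (windows != spacer_arr).sum(axis=1)
    hits = []
    for pos in np.nonzero(mm <= max_mm)[0]:
        pos = int(pos)
        if require_pam and not _pam_ok(seq, pos):
            continue
        hits.append((pos, int(mm[pos])))
    return hits


def find_target_sites(
    spacer: str,
    db: Sequence[SequenceRecord],
    max_mm: int = 0,
    require_pam: bool = True,
) -> list[MatchHit]:
    """All protospacer matches of ``spacer`` in ``db`` within ``max_mm``.

    Both strands are scanned; minus-strand positions refer to the
    reverse-complemented sequence's own 5'->3' orientation.  Hamming
    distance only (no indel bulges), counted over the 20 spacer positions;
    with ``require_pam`` the adjacent 3-mer must be NGG on the hit strand.
    """
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN or set(spacer) - set("ACGT"):
        raise SpacerError(
            f"spacer must be {SPACER_LEN} nt over ACGT, got {spacer!r}"
        )
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    spacer_arr = np.array([_BASE_ORD[b] for b in spacer], dtype=np.uint8)

    hits: list[MatchHit] = []
    for rec in db:
        for strand, seq in (("+", rec.seq), ("-", reverse_complement(rec.seq))):
            for pos, mm in _scan_one_strand(spacer_arr, seq, max_mm, require_pam):
                hits.append(
                    MatchHit(rec.id, pos, strand, mm, pam_ok=True)
                    if require_pam
                    else MatchHit(
                        rec.id,
                        pos,
                        strand,
                        mm,
                        pam_ok=_pam_ok(seq, pos),
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


def _pam_ok(seq: str, pos: int) -> bool:
    pam = seq[pos + SPACER_LEN: pos + SPACER_LEN + PAM_LEN]
    return len(pam) == PAM_LEN and pam[1:] == "GG"


def conservation_coverage(
    spacer: str,
    db: Sequence[SequenceRecord],
    max_mm: int = 0,
    rank: str = "family",
    require_pam: bool = True,
) -> CoverageReport:
    """Fraction of database sequences carrying a qualifying spacer site.

    The per-taxon breakdown buckets sequences without an annotation at the
    requested rank under ``"unannotated"`` so the bucket counts sum exactly
    to the totals.
    """
    if not db:
        raise ValueError("empty database")
    hits = find_target_sites(spacer, db, max_mm=max_mm, require_pam=require_pam)
    hit_ids = {h.seq_id for h in hits}
    per_taxon: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    miss = []
    for rec in db:
        taxon = rec.lineage.name_at(rank) if rec.lineage else ""
        key = taxon or "unannotated"
        per_taxon[key][0] += 1
        if rec.id in hit_ids:
            per_taxon[key][1] += 1
        else:
            miss.append(rec.id)
    return CoverageReport(
        n_db=len(db),
        n_hit=len(hit_ids),
        per_taxon={k: (v[0], v[1]) for k, v in per_taxon.items()},
        miss_ids=miss,
        rank=rank,
    )


DEFAULT_EXCLUDE_TERMS = ("Chloroplast", "Mitochondria")


def offtarget_screen(
    spacer: str,
    db: Sequence[SequenceRecord],
    max_mm: int = 2,
    exclude_terms: Iterable[str] = DEFAULT_EXCLUDE_TERMS,
) -> OfftargetReport:
    """Screen a database for unintended cleavage sites.

    Organellar entries (by default, lineages containing "Chloroplast" or
    "Mitochondria") are intended targets or known organellar homologues,
    not off-targets; their hits are reported separately and never counted
    in ``fraction_flagged``.
    """
    terms = list(exclude_terms)
    hits = find_target_sites(spacer, db, max_mm=max_mm, require_pam=True)
    lineages = {rec.id: rec.lineage for rec in db}
    report = OfftargetReport(
        n_db=len(db), max_mm=max_mm, near_hits={k: [] for k in range(1, max_mm + 1)}
    )
    flagged = set()
    for h in hits:
        lin = lineages.get(h.seq_id)
        if lin is not None and any(lin.contains(t) for t in terms):
            report.excluded_hits.append(h)
            continue
        flagged.add(h.seq_id)
        if h.mismatches == 0:
            report.exact_hits.append(h)
        else:
            report.near_hits[h.mismatches].append(h)
    report.flagged_ids = sorted(flagged)
    return report


def _primer_regex(primer: str) -> re.Pattern:
    parts = []
    for base in primer.upper():
        if base not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {base!r} in primer")
        letters = sorted(IUPAC_CODES[base])
        if base == "N":
            letters.append("N")  # only an N pattern may match a target N
        parts.append("[" + "".join(letters) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def primer_sites(primer: str, record: SequenceRecord) -> list[tuple[int, str]]:
    """Zero-mismatch degenerate-primer matches on both strands.

    Returns plus-strand 0-based start positions.  Plus-strand entries are
    sites the primer binds directly (forward orientation); minus-strand
    entries are positions where the reverse complement of the primer occurs
    (i.e. the primer binds the minus strand, as a reverse primer does).
    """
    seq = record.seq
    sites = [(m.start(), "+") for m in _primer_regex(primer).finditer(seq)]
    rc_pat = _primer_regex(reverse_complement(primer))
    sites += [(m.start(), "-") for m in rc_pat.finditer(seq)]
    sites.sort()
    return sites


def _covered_plus_orientation(
    spacer: str,
    outer: tuple[str, str],
    inner: tuple[str, str],
    rec: SequenceRecord,
) -> bool:
    """Coverage check assuming the record runs 5'->3' on the plus strand."""
    fwd_out, rev_out = outer
    fwd_in, rev_in = inner
    f27 = [p for p, s in primer_sites(fwd_out, rec) if s == "+"]
    f515 = [p for p, s in primer_sites(fwd_in, rec) if s == "+"]
    r806 = [p for p, s in primer_sites(rev_in, rec) if s == "-"]
    r1492 = [p for p, s in primer_sites(rev_out, rec) if s == "-"]
    if not (f27 and f515 and r806 and r1492):
        return False
    sites = find_target_sites(spacer, [rec], max_mm=0, require_pam=True)
    spacer_blocks = []
    for h in sites:
        if h.strand == "+":
            spacer_blocks.append(h.position)
        else:
            spacer_blocks.append(len(rec.seq) - h.position - SPACER_LEN - PAM_LEN)
    block = SPACER_LEN + PAM_LEN
    for a in f27:
        for b in f515:
            if b < a + len(fwd_out):
                continue
            for g in spacer_blocks:
                if g < b + len(fwd_in):
                    continue
                for c in r806:
                    if c < g + block:
                        continue
                    for d in r1492:
                        if d >= c + len(rev_in):
                            return True
    return False


def joint_coverage(
    spacer: str,
    db: Sequence[SequenceRecord],
    outer_primers: tuple[str, str] = (PRIMERS["27F"], PRIMERS["1492R"]),
    inner_primers: tuple[str, str] = (PRIMERS["515F"], PRIMERS["806R"]),
    rank: str = "family",
    min_length: int = 0,
    export_fasta: str | Path | None = None,
) -> CoverageReport:
    """Sequences amplifiable by the whole nested design AND cut by the guide.

    A sequence counts as covered iff it carries, in consistent order along
    one orientation: an outer forward site, an inner forward site, an exact
    spacer+NGG site, an inner reverse site, and an outer reverse site.
    Records stored in antisense orientation are recognised by also testing
    the reverse complement.  Sequences shorter than the full primer span
    simply count as uncovered; ``min_length`` optionally pre-filters them
    out of the denominator.
    """
    if min_length:
        db = [r for r in db if len(r) >= min_length]
    covered = []
    per_taxon: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    miss = []
    for rec in db:
        ok = _covered_plus_orientation(spacer, outer_primers, inner_primers, rec)
        if not ok:
            flipped = SequenceRecord(
                rec.id, rec.description, reverse_complement(rec.seq), rec.lineage
            )
            ok = _covered_plus_orientation(
                spacer, outer_primers, inner_primers, flipped
            )
        taxon = rec.lineage.name_at(rank) if rec.lineage else ""
        key = taxon or "unannotated"
        per_taxon[key][0] += 1
        if ok:
            per_taxon[key][1] += 1
            covered.append(rec)
        else:
            miss.append(rec.id)
    if export_fasta is not None:
        write_fasta(covered, export_fasta)
    return CoverageReport(
        n_db=len(db),
        n_hit=len(covered),
        per_taxon={k: (v[0], v[1]) for k, v in per_taxon.items()},
        miss_ids=miss,
        rank=rank,
    )


def assemble_sgrna_template(
    universal_oligo: str = UNIVERSAL_OLIGO,
    specific_oligo: str = SPECIFIC_OLIGO,
    min_overlap: int = 6,
) -> SgrnaTemplate:
    """Fuse the two sgRNA synthesis oligos over their shared linker.

    The specific oligo's 3' end must overlap the 5' end of the reverse
    complement of the universal oligo (the linker through which the
    overlap-extension PCR joins them).  The longest such overlap of at
    least ``min_overlap`` nt is used.
    """
    spec = specific_oligo.upper().replace("U", "T")
    univ_rc = reverse_complement(universal_oligo.upper().replace("U", "T"))
    best = 0
    for k in range(min(len(spec), len(univ_rc)), min_overlap - 1, -1):
        if spec[-k:] == univ_rc[:k]:
            best = k
            break
    if best == 0:
        raise SpacerError(
            f"no linker found: no suffix/prefix overlap >= {min_overlap} nt"
        )
    return SgrnaTemplate(seq=spec + univ_rc[best:], overlap=best)
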