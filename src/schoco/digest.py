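"""In-silico Cas9 digestion of amplicon pools.

The depletion mechanism: full-length (V1-V9) 16S amplicons from a host cell
are digested with Cas9 loaded with a guide targeting the central V4 region
of the host chloroplast 16S.  A cut between the inner (V4) primer sites
leaves neither fragment amplifiable in the subsequent V4 library PCR, so
cut molecules drop out of the sequencing pool and the surviving pool is
enriched for everything the guide does not hit.

Cleavage is blunt between spacer positions 17 and 18 — three base pairs 5'
of the PAM — the canonical SpCas9 cut geometry.  Partial digestion is
modeled as one Bernoulli trial per molecule with success probability
``efficiency``; with removal-then-renormalisation this gives the closed
form ``c(1-e)/(1-c*e)`` for the expected post-digestion fraction of a
cuttable category at pre-digestion fraction ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from schoco.formats import SequenceRecord, reverse_complement
from schoco.guide_screen import (
    PAM_LEN,
    PRIMERS,
    SPACER_LEN,
    find_target_sites,
    primer_sites,
)

CUT_OFFSET = 17  # cut falls after this many spacer bases (blunt, 3 bp 5' of PAM)

CATEGORIES = ("chloroplast", "bacteria", "mitochondria", "other")


@dataclass(frozen=True)
class Amplicon:
    """One labeled amplicon molecule in a digestion pool."""

    seq: str
    label: str
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(
                f"label must be one of {CATEGORIES}, got {self.label!r}"
            )


@dataclass
class DigestResult:
    """Fragments produced by cutting one sequence."""

    fragments: list[str]
    cut_positions: list[int]

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)


@dataclass
class DepletionStats:
    """Category composition of a pool before and after digestion."""

    pre_proportions: dict[str, float]
    post_proportions: dict[str, float]
    efficiency: float
    n_molecules: int
    n_cut: int = 0
    n_amplifiable_post: int = 0

    def __post_init__(self) -> None:
        for props in (self.pre_proportions, self.post_proportions):
            if props:
                total = sum(props.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"proportions sum to {total}, expected 1"
                    )


def cut_positions(seq: str, spacer: str, require_pam: bool = True) -> list[int]:
    """Plus-strand coordinates of Cas9 blunt cuts for exact spacer sites.

    A plus-strand protospacer starting at ``s`` is cut at ``s + 17`` (the
    coordinate counts bases left of the cut).  A minus-strand protospacer
    whose plus-strand block (PAM complement + spacer complement) starts at
    ``p`` is cut at ``p + 3 + 3`` = ``p + PAM_LEN + (20 - 17)`` — three
    bases 3'-ward of the minus-strand PAM in plus coordinates.
    """
    hits = find_target_sites(spacer, [SequenceRecord("q", "", seq)],
                             max_mm=0, require_pam=require_pam)
    cuts = set()
    for h in hits:
        if h.strand == "+":
            cuts.add(h.position + CUT_OFFSET)
        else:
            # h.position is on the reverse complement; map back.
            block_start = len(seq) - h.position - SPACER_LEN - PAM_LEN
            cuts.add(block_start + PAM_LEN + (SPACER_LEN - CUT_OFFSET))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_sequence(
    seq: str, spacer: str, require_pam: bool = True
) -> DigestResult:
    """Cut a sequence at every exact spacer site on either strand.

    Zero sites yield a single fragment equal to the input; fragments always
    concatenate back to the input.
    """
    cuts = cut_positions(seq, spacer, require_pam=require_pam)
    fragments = []
    prev = 0
    for c in cuts:
        fragments.append(seq[prev:c])
        prev = c
    fragments.append(seq[prev:])
    return DigestResult(fragments=fragments, cut_positions=cuts)


def amplifiable(
    fragment: str,
    fwd_primer: str = PRIMERS["515F"],
    rev_primer: str = PRIMERS["806R"],
) -> bool:
    """Can this fragment template the inner (V4) library PCR?

    True iff a forward-primer site lies fully 5' of a reverse-primer site
    (the reverse primer matched as its reverse complement on the plus
    strand).
    """
    rec = SequenceRecord("f", "", fragment) if fragment else None
    if rec is None:
        return False
    fwd = [p for p, s in primer_sites(fwd_primer, rec) if s == "+"]
    rev = [p for p, s in primer_sites(rev_primer, rec) if s == "-"]
    return any(f + len(fwd_primer) <= r for f in fwd for r in rev)


def pool_depletion(
    pool: Sequence[Amplicon],
    spacer: str,
    efficiency: float,
    inner_primers: tuple[str, str] = (PRIMERS["515F"], PRIMERS["806R"]),
    seed: int | np.random.Generator = 0,
) -> tuple[list[Amplicon], DepletionStats]:
    """Digest a pool and report the change in category composition.

    Every molecule carrying at least one exact spacer+PAM site is cut with
    probability ``efficiency`` (independent Bernoulli per molecule).  The
    post pool contains the molecules that can still template the inner
    (V4) PCR: uncut molecules with both inner sites, plus any cut molecule
    one of whose fragments retains both sites (does not happen when the
    cut falls between them).
    """
    if not pool:
        raise ValueError("empty pool")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must be in [0, 1], got {efficiency}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fwd, rev = inner_primers

    pre = _proportions([m.label for m in pool])
    survivors: list[Amplicon] = []
    n_cut = 0
    for mol in pool:
        cuts = cut_positions(mol.seq, spacer)
        if cuts and rng.random() < efficiency:
            n_cut += 1
            frags = digest_sequence(mol.seq, spacer).fragments
            keep = [f for f in frags if amplifiable(f, fwd, rev)]
            survivors.extend(
                Amplicon(f, mol.label, mol.taxon) for f in keep
            )
        else:
            if amplifiable(mol.seq, fwd, rev):
                survivors.append(mol)

    post = _proportions([m.label for m in survivors])
    return survivors, DepletionStats(
        pre_proportions=pre,
        post_proportions=post,
        efficiency=efficiency,
        n_molecules=len(pool),
        n_cut=n_cut,
        n_amplifiable_post=len(survivors),
    )


def expected_post_fraction(c: float, e: float) -> float:
    """Closed-form expected post-digestion fraction of a cuttable category.

    Removal of a ``c`` fraction with per-molecule probability ``e``
    followed by renormalisation over survivors gives
    ``c(1-e) / (1 - c*e)``.
    """
    return c * (1.0 - e) / (1.0 - c * e)


def _proportions(labels: Sequence[str]) -> dict[str, float]:
    if not labels:
        return {}
    n = len(labels)
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0
    return {k: v / n for k, v in out.items()}
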