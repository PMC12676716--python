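"""Synthetic paired single-cell datasets and toy reference databases.

The generator emulates the statistical structure of paired control
(SC-seq) and Cas9-treated (SCHoCO-seq) single-cell 16S amplicon libraries
of a diatom host:

- each cell's read pool is dominated by a chloroplast fraction ``c`` drawn
  from a Beta distribution (control mean 71.4%, sd 14.3%), with a small
  "other" fraction (mitochondria plus order-unannotated reads) and the
  remainder bacterial;
- the bacterial compartment is a long-tailed (log-normal) community of
  named genera, a core subset shared across host strains plus
  strain-unique taxa, with per-cell log-normal abundance jitter so no
  genus is consistently present across replicates;
- the Cas9 treatment removes each chloroplast template with probability
  ``e`` (the digestion efficiency) and the library is re-drawn to a fresh
  depth, so the expected treated chloroplast share follows the closed form
  ``c(1-e)/(1-c*e)``.

Preset constants are frozen results of ``scripts/calibrate_presets.py``:
the Beta fractions come straight from the observed control composition,
``e`` solves the treated-arm mean chloroplast share (17.5%) under the
control Beta spread, and each strain's community size / tail shape are
chosen so that the full filtering + SRS pipeline reproduces the observed
per-strain bacterial richness in both arms.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from schoco.formats import (
    RANKS,
    AsvTable,
    SampleMeta,
    SequenceRecord,
    TaxonomyLineage,
    parse_taxonomy_header,
    reverse_complement,
    write_fasta,
)
from schoco.guide_screen import (
    IUPAC_CODES,
    PRIMERS,
    SELECTED_SPACER,
    find_target_sites,
)

TREATED = "SCHoCO-seq"
CONTROL = "SC-seq"


def _lineage(*names: str) -> TaxonomyLineage:
    padded = (list(names) + [""] * len(RANKS))[: len(RANKS)]
    return TaxonomyLineage(tuple(zip(RANKS, padded)), dialect="silva")


CHLOROPLAST_LINEAGE = _lineage(
    "Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast"
)
MITOCHONDRIA_LINEAGE = _lineage(
    "Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
    "Mitochondria",
)
UNANNOTATED_LINEAGE = _lineage("Bacteria", "Proteobacteria")

# (phylum, class, order, family, genus) of marine heterotrophs typical of
# diatom phycospheres.  The first eight form the core shared across strains.
_GENUS_POOL: list[tuple[str, str, str, str, str]] = [
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales",
     "Rhodobacteraceae", "Sulfitobacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales",
     "Colwelliaceae", "Colwellia"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales",
     "Rhodobacteraceae", "Roseobacter"),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales",
     "Flavobacteriaceae", "Polaribacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales",
     "Alteromonadaceae", "Glaciecola"),
    ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales",
     "Alteromonadaceae", "Paraglaciecola"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
     "Marinobacteraceae", "Marinobacter"),
    ("Bacteroidota", "Rhodothermia", "Balneolales",
     "Balneolaceae", "Balneola"),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales",
     "Flavobacteriaceae", "Aurantivirga"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
     "Phyllobacteriaceae", "Lentilitoribacter"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales",
     "Rhodobacteraceae", "Octadecabacter"),
    ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
     "Sphingomonadaceae", "Sphingomonas"),
    ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales",
     "Methylophilaceae", "Methylophilus"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
     "Rhizobiaceae", "Rhizobium"),
    ("Proteobacteria", "Alphaproteobacteria", "Parvibaculales",
     "Parvibaculaceae", "Parvibaculum"),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales",
     "Cryomorphaceae", "Crocinitomix"),
    ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales",
     "Rubritaleaceae", "Rubritalea"),
    ("Proteobacteria", "Gammaproteobacteria", "Cellvibrionales",
     "Halieaceae", "Haliea"),
]

N_CORE_GENERA = 8


@dataclass(frozen=True)
class CommunityProfile:
    """A strain's bacterial community: taxa with relative abundances."""

    strain: str
    taxa: tuple[tuple[str, float], ...]  # (asv id, relative abundance)
    lineages: dict[str, TaxonomyLineage]
    tail_shape: float

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class Preset:
    """Frozen study conditions for one simulated strain.

    Fraction distributions are Beta, parameterised by (mean, sd) via
    moment matching and clamped to (0.001, 0.999); depths are log-normal
    with a hard floor so the default depth filter cannot empty a dataset.
    """

    name: str
    strain: str
    chl_mean: float = 0.714
    chl_sd: float = 0.143
    other_mean: float = 0.027
    other_sd: float = 0.021
    efficiency: float = 0.938
    depth_median: float = 25000.0
    depth_sigma: float = 0.30
    depth_min: int = 12000
    n_taxa: int = 26
    sigma: float = 1.7
    core_frac: float | None = 0.75
    core_sigma: float = 0.4
    cell_sigma: float = 0.6
    community_seed: int = 2024
    n_cells: int = 62


#: Frozen per-strain presets (constants from scripts/calibrate_presets.py).
PRESETS: dict[str, Preset] = {
    "tgravida-a1": Preset(name="tgravida-a1", strain="A1",
                          n_taxa=28, sigma=1.7, core_frac=0.9,
                          core_sigma=0.4, cell_sigma=0.6, community_seed=7),
    "tgravida-a2": Preset(name="tgravida-a2", strain="A2",
                          n_taxa=14, sigma=2.8, core_frac=None,
                          cell_sigma=1.2, community_seed=3),
    "tgravida-a5": Preset(name="tgravida-a5", strain="A5",
                          n_taxa=14, sigma=2.4, core_frac=None,
                          cell_sigma=1.2, community_seed=6),
}


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b) parameters for a given mean and sd."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    var = sd * sd
    kappa = mean * (1.0 - mean) / var - 1.0
    if kappa <= 0:
        raise ValueError("sd too large for a Beta distribution")
    return mean * kappa, (1.0 - mean) * kappa


def _draw_fraction(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = beta_from_mean_sd(mean, sd)
    return float(np.clip(rng.beta(a, b), 0.001, 0.999))


def _rng_for(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode())])


def make_community(
    strain: str,
    n_taxa: int,
    sigma: float,
    seed: int = 0,
    n_core: int = N_CORE_GENERA,
    core_frac: float | None = 0.75,
    core_sigma: float = 0.4,
) -> CommunityProfile:
    """Draw a strain-level bacterial community profile.

    The first ``n_core`` genera of the pool are shared by every strain;
    the remaining taxa are strain-specific picks (synthetic genera are
    appended when ``n_taxa`` exceeds the named pool).  The community has
    two compartments: the core genera split a ``core_frac`` share of the
    bacterial reads with mild log-normal variation (``core_sigma``) — the
    consistently abundant phycosphere associates — while the remaining
    taxa form a long log-normal tail of shape ``sigma`` over the rest.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _rng_for(seed, f"community:{strain}")
    n_core = min(n_core, n_taxa)
    final = list(_GENUS_POOL[:n_core])
    # strain-unique picks: disjoint slices of the named pool per known
    # strain, synthetic strain-tagged genera beyond that
    uniques = _GENUS_POOL[N_CORE_GENERA:]
    slice_idx = {"A1": 0, "A2": 1, "A5": 2}.get(strain)
    pool = uniques[slice_idx::3] if slice_idx is not None else []
    k = 0
    while len(final) < n_taxa:
        if k < len(pool):
            final.append(pool[k])
        else:
            i = k - len(pool)
            final.append(
                ("Proteobacteria", "Gammaproteobacteria", "Synthetales",
                 f"Synthetaceae{strain}{i}", f"Synthetica{strain}{i}")
            )
        k += 1

    n_tail = n_taxa - n_core
    if core_frac is None:
        # single-compartment community: one log-normal tail over all taxa
        weights = rng.lognormal(0.0, sigma, size=n_taxa)
        weights /= weights.sum()
    else:
        core_w = rng.lognormal(0.0, core_sigma, size=n_core)
        core_w /= core_w.sum()
        if n_tail > 0:
            tail_w = rng.lognormal(0.0, sigma, size=n_tail)
            tail_w /= tail_w.sum()
            weights = np.concatenate(
                (core_frac * core_w, (1.0 - core_frac) * tail_w)
            )
        else:
            weights = core_w
    taxa = []
    lineages = {}
    for (phylum, cls, order, family, genus), w in zip(final, weights):
        asv_id = f"b{strain}.{genus}"
        taxa.append((asv_id, float(w)))
        lineages[asv_id] = _lineage(
            "Bacteria", phylum, cls, order, family, genus
        )
    return CommunityProfile(
        strain=strain, taxa=tuple(taxa), lineages=lineages, tail_shape=sigma
    )


def _cell_state(
    preset: Preset,
    community: CommunityProfile,
    cell_id: str,
    seed: int,
) -> tuple[float, float, np.ndarray]:
    """Latent per-cell draws shared by both treatments of one cell."""
    rng = _rng_for(seed, f"cell:{cell_id}")
    c = _draw_fraction(rng, preset.chl_mean, preset.chl_sd)
    o = _draw_fraction(rng, preset.other_mean, preset.other_sd)
    o = min(o, (1.0 - c) / 2.0)
    base = np.array([w for _, w in community.taxa])
    jitter = rng.lognormal(0.0, preset.cell_sigma, size=len(base))
    w = base * jitter
    return c, o, w / w.sum()


def _host_asv_ids(strain: str) -> list[str]:
    return [f"chl.{strain}", f"mito.{strain}", f"unk.{strain}"]


def simulate_cell(
    preset: Preset,
    strain: str | None = None,
    cell_id: str = "cell01",
    treatment: str = CONTROL,
    seed: int = 0,
    community: CommunityProfile | None = None,
) -> tuple[pd.Series, dict[str, TaxonomyLineage], SampleMeta, dict]:
    """Simulate one sequencing library of one isolated cell.

    Returns (counts, taxonomy, metadata, truth).  The latent cell state
    (chloroplast fraction, other fraction, per-cell community weights) is
    derived from ``(seed, cell_id)`` only, so calling with both treatments
    yields a properly paired sample sharing the same underlying cell.
    """
    strain = strain or preset.strain
    if community is None:
        community = make_community(
            strain, preset.n_taxa, preset.sigma, preset.community_seed,
            core_frac=preset.core_frac, core_sigma=preset.core_sigma,
        )
    c, o, w = _cell_state(preset, community, cell_id, seed)

    chl_id, mito_id, unk_id = _host_asv_ids(strain)
    asv_ids = [chl_id, mito_id, unk_id] + [a for a, _ in community.taxa]
    b = 1.0 - c - o
    pi = np.concatenate(([c, 0.6 * o, 0.4 * o], b * w))

    if treatment == TREATED:
        pi = pi.copy()
        pi[0] *= 1.0 - preset.efficiency
        pi = pi / pi.sum()
    elif treatment != CONTROL:
        raise ValueError(f"unknown treatment {treatment!r}")

    sample_id = f"{cell_id}.{'T' if treatment == TREATED else 'C'}"
    rng = _rng_for(seed, f"library:{sample_id}")
    depth = int(
        max(
            preset.depth_min,
            rng.lognormal(np.log(preset.depth_median), preset.depth_sigma),
        )
    )
    counts = pd.Series(
        rng.multinomial(depth, pi), index=asv_ids, name=sample_id
    )

    taxonomy = {
        chl_id: CHLOROPLAST_LINEAGE,
        mito_id: MITOCHONDRIA_LINEAGE,
        unk_id: UNANNOTATED_LINEAGE,
        **community.lineages,
    }
    meta = SampleMeta(
        sample_id=sample_id,
        cell_id=cell_id,
        strain=strain,
        condition="full",
        prep="SC-PCR",
        treatment=treatment,
    )
    truth = {
        "cell_id": cell_id,
        "treatment": treatment,
        "chl_fraction_pre": c,
        "other_fraction_pre": o,
        "template_proportions": dict(zip(asv_ids, map(float, pi))),
        "depth": depth,
    }
    return counts, taxonomy, meta, truth


def simulate_paired_dataset(
    preset: Preset | str,
    seed: int = 0,
    n_cells: int | None = None,
) -> tuple[AsvTable, dict]:
    """Simulate ``n_cells`` control/treated library pairs of one strain.

    Returns the assembled :class:`AsvTable` (2 x n_cells sample columns)
    and a ground-truth ledger holding every latent draw, for parameter
    recovery tests.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    n_cells = preset.n_cells if n_cells is None else n_cells
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    community = make_community(
        preset.strain, preset.n_taxa, preset.sigma, preset.community_seed,
        core_frac=preset.core_frac, core_sigma=preset.core_sigma,
    )
    columns = []
    taxonomy: dict[str, TaxonomyLineage] = {}
    samples: dict[str, SampleMeta] = {}
    ledger: dict = {
        "preset": asdict(preset),
        "seed": int(seed),
        "expected_post_chl_closed_form": None,
        "cells": {},
    }
    for i in range(1, n_cells + 1):
        cell_id = f"{preset.strain}c{i:03d}"
        for treatment in (CONTROL, TREATED):
            counts, tax, meta, truth = simulate_cell(
                preset, preset.strain, cell_id, treatment, seed, community
            )
            columns.append(counts)
            taxonomy.update(tax)
            samples[meta.sample_id] = meta
            ledger["cells"].setdefault(cell_id, {})[treatment] = truth

    e = preset.efficiency
    post = [
        t[CONTROL]["chl_fraction_pre"] * (1 - e)
        / (1 - t[CONTROL]["chl_fraction_pre"] * e)
        for t in ledger["cells"].values()
    ]
    ledger["expected_post_chl_closed_form"] = float(np.mean(post))

    counts_df = (
        pd.concat(columns, axis=1).fillna(0).astype("int64")
    )
    table = AsvTable(counts=counts_df, taxonomy=taxonomy, samples=samples)
    return table, ledger


def write_dataset(table: AsvTable, ledger: dict, out_dir: str | Path) -> None:
    """Write counts/taxonomy/metadata TSVs plus the truth ledger JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.counts.rename_axis("asv_id").to_csv(out / "counts.tsv", sep="\t")
    tax = pd.DataFrame(
        {
            "taxonomy": {
                a: ";".join(lin.names()).rstrip(";")
                for a, lin in table.taxonomy.items()
            }
        }
    )
    tax.rename_axis("asv_id").to_csv(out / "taxonomy.tsv", sep="\t")
    meta = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "cell_id": m.cell_id,
                "strain": m.strain,
                "condition": m.condition,
                "prep": m.prep,
                "treatment": m.treatment,
            }
            for m in table.samples.values()
        ]
    ).set_index("sample_id")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1)


# ---------------------------------------------------------------------------
# toy reference databases


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _expand_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_CODES[b]))
        for b in primer
    )


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def make_toy_chloroplast(seed: int = 0) -> SequenceRecord:
    """A synthetic chloroplast 16S stand-in with all workflow sites in order.

    Layout along the plus strand: outer forward (27F) site, inner forward
    (515F) site, the selected spacer followed by an AGG PAM (inside the
    "V4" window), inner reverse (806R) site, outer reverse (1492R) site.
    """
    rng = np.random.default_rng([seed, 7001])
    while True:
        parts = [
            _random_dna(rng, 30),
            _expand_primer(PRIMERS["27F"], rng),
            _random_dna(rng, 120),
            _expand_primer(PRIMERS["515F"], rng),
            _random_dna(rng, 60),
            SELECTED_SPACER + "AGG",
            _random_dna(rng, 60),
            reverse_complement(_expand_primer(PRIMERS["806R"], rng)),
            _random_dna(rng, 150),
            reverse_complement(_expand_primer(PRIMERS["1492R"], rng)),
            _random_dna(rng, 30),
        ]
        seq = "".join(parts)
        rec = SequenceRecord(
            "toychl1",
            "toychl1|Eukaryota;Stramenopiles;Bacillariophyta;"
            "Coscinodiscophyceae;Thalassiosirales;Thalassiosiraceae;"
            "Thalassiosira",
            seq,
        )
        hits = find_target_sites(SELECTED_SPACER, [rec], max_mm=2,
                                 require_pam=False)
        if len(hits) == 1:  # no accidental near-matches in the padding
            rec.lineage = parse_taxonomy_header(rec.description, "phytoref")
            return rec


def make_toy_refdb(seed: int = 0, out_dir: str | Path | None = None
                   ) -> list[SequenceRecord]:
    """Toy chloroplast + decoy prokaryote sequences with planted sites.

    Decoys (all ~300 nt, SILVA-style headers) carry protospacers at 1, 2,
    and 3 mismatches with an NGG PAM, an exact protospacer without PAM,
    and an exact organellar (chloroplast-annotated) site; two decoys have
    no planted site at all.  The builder verifies by brute scan that no
    accidental site within 2 mismatches exists beyond the planted ones.
    """
    rng = np.random.default_rng([seed, 7002])
    records = [make_toy_chloroplast(seed)]

    plans = [
        ("dec_mm1", 1, "TGG",
         "Bacteria;Proteobacteria;Gammaproteobacteria;Alteromonadales;"
         "Colwelliaceae;Colwellia"),
        ("dec_mm2", 2, "AGG",
         "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;"
         "Flavobacteriaceae;Polaribacter"),
        ("dec_mm3", 3, "GGG",
         "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;"
         "Rhodobacteraceae;Sulfitobacter"),
        ("dec_nopam", 0, "ATT",
         "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;"
         "Sphingomonadaceae;Sphingomonas"),
        ("dec_chloro", 0, "AGG",
         "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast"),
        ("dec_plain1", None, None,
         "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;"
         "Marinobacteraceae;Marinobacter"),
        ("dec_plain2", None, None,
         "Bacteria;Verrucomicrobiota;Verrucomicrobiae;Verrucomicrobiales;"
         "Rubritaleaceae;Rubritalea"),
    ]
    for name, n_mm, pam, lineage in plans:
        while True:
            left = _random_dna(rng, 140)
            right = _random_dna(rng, 140)
            if n_mm is None:
                seq = left + right
            else:
                positions = sorted(
                    rng.choice(len(SELECTED_SPACER), size=n_mm, replace=False)
                ) if n_mm else []
                proto = _mutate(SELECTED_SPACER, positions, rng)
                seq = left + proto + pam + right
            rec = SequenceRecord(name, f"{name}.1.{len(seq)} {lineage}", seq)
            hits = find_target_sites(
                SELECTED_SPACER, [rec], max_mm=2, require_pam=False
            )
            expected = 1 if (n_mm is not None and n_mm <= 2) else 0
            if len(hits) == expected:
                rec.lineage = parse_taxonomy_header(rec.description, "silva")
                records.append(rec)
                break

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records[:1], out / "toy_chloroplast.fasta")
        write_fasta(records[1:], out / "toy_decoys.fasta")
    return records
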