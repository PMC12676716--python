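"""Single-cell ASV analysis: filters, scaling, diversity, depth simulation,
and the Poisson-GLM detection model.

The processing order mirrors the intended analysis protocol:

1. remove contaminant / non-marine ASVs, then zero per-sample entries below
   a relative-abundance floor (default 0.25% of the sample's reads);
2. exclude shallow samples (below 10 000 reads or below the lower 10%
   depth quantile of the dataset);
3. scale every sample to a common library size ``Cmin`` by ranked
   subsampling (SRS): counts are scaled by ``Cmin/depth``, integer parts
   kept, and the remaining counts assigned one-by-one to ASVs ranked by
   descending fractional part (seeded uniform tie-break);
4. normalise by a power transform (default fourth root).

Diversity metrics (richness, Shannon, Bray-Curtis), the sequencing-depth
subsampling simulation, and the incidence-rate-ratio (IRR) detection model
operate on these tables.  The IRR of a bacterial family is ``exp(b1)`` of
a Poisson log-link GLM ``log mu = b0 + b1 * treated`` fitted to per-sample
detection counts; it estimates the fold-change in the probability of
detecting that family under Cas9 treatment relative to control.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats
import statsmodels.api as sm

from schoco.formats import AsvTable, SampleMeta, TaxonomyLineage

logger = logging.getLogger(__name__)

CATEGORIES = ("bacteria", "chloroplast", "mitochondria", "other")

DEFAULT_DEPTHS = (500, 1000, 5000, 10000)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample stream derived from (seed, sample id)."""
    return np.random.default_rng([int(seed), zlib.crc32(sample_id.encode())])


# ---------------------------------------------------------------------------
# classification


def classify_asvs(table: AsvTable) -> pd.Series:
    """Assign each ASV to one of bacteria / chloroplast / mitochondria / other.

    Chloroplast and mitochondrial ASVs are recognised by a rank name equal
    to "Chloroplast" / "Mitochondria" anywhere in the lineage (the SILVA
    convention places them at the order and family rank respectively).
    Remaining ASVs count as bacteria only when the domain is Bacteria and
    an order-level annotation is present; everything else — including
    bacteria unannotated below class — is "other".
    """
    calls = {}
    for asv in table.asv_ids:
        lin = table.taxonomy.get(asv) or TaxonomyLineage.empty()
        names = set(lin.names())
        if "Chloroplast" in names:
            calls[asv] = "chloroplast"
        elif "Mitochondria" in names:
            calls[asv] = "mitochondria"
        elif lin.name_at("domain") == "Bacteria" and lin.name_at("order"):
            calls[asv] = "bacteria"
        else:
            calls[asv] = "other"
    return pd.Series(calls, name="category")


def category_proportions(
    table: AsvTable,
    calls: pd.Series | None = None,
    fold_mitochondria: bool = True,
) -> pd.DataFrame:
    """Per-sample read percentages by ASV category.

    With ``fold_mitochondria`` (the summary-table convention) mitochondrial
    reads are folded into "other", leaving three columns that sum to 100
    per sample.
    """
    if calls is None:
        calls = classify_asvs(table)
    cats = calls.reindex(table.counts.index)
    if fold_mitochondria:
        cats = cats.replace("mitochondria", "other")
    grouped = table.counts.groupby(cats).sum()
    order = (
        ["bacteria", "chloroplast", "other"]
        if fold_mitochondria
        else list(CATEGORIES)
    )
    grouped = grouped.reindex(order, fill_value=0)
    depths = table.counts.sum(axis=0)
    return (grouped / depths * 100.0).T


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterLog:
    """Record of what the filters removed, for reporting."""

    removed_asvs: list[str] = field(default_factory=list)
    zeroed: list[tuple[str, str]] = field(default_factory=list)
    dropped_all_zero: list[str] = field(default_factory=list)
    excluded_samples: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def filter_asvs(
    table: AsvTable,
    min_rel: float = 0.0025,
    contaminants: Iterable[str] = (),
    nonmarine: Iterable[str] = (),
) -> tuple[AsvTable, FilterLog]:
    """Contaminant removal and per-sample relative-abundance floor.

    ASVs whose id matches, or whose lineage contains, an entry of the
    contaminant or non-marine lists are removed everywhere.  Then any
    per-sample entry contributing strictly less than ``min_rel`` of that
    sample's reads is zeroed (an entry at exactly the threshold is kept).
    All-zero rows are dropped.  Idempotent: zeroing only raises the
    surviving entries' relative contributions.
    """
    log = FilterLog()
    terms = list(contaminants) + list(nonmarine)

    def _matches(asv: str) -> bool:
        if asv in terms:
            return True
        lin = table.taxonomy.get(asv)
        return lin is not None and any(lin.contains(t) for t in terms if t)

    keep = [a for a in table.asv_ids if not _matches(a)]
    log.removed_asvs = [a for a in table.asv_ids if a not in set(keep)]
    counts = table.counts.loc[keep].copy()

    depths = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts.div(depths.replace(0, np.nan), axis=1)
    mask = (rel < min_rel) & (counts > 0)
    for asv, sid in zip(*np.nonzero(mask.values)):
        log.zeroed.append((counts.index[asv], counts.columns[sid]))
    counts = counts.where(~mask, 0)

    nonzero = counts.sum(axis=1) > 0
    log.dropped_all_zero = list(counts.index[~nonzero])
    counts = counts.loc[nonzero]

    out = AsvTable(
        counts=counts,
        taxonomy={a: table.taxonomy[a] for a in counts.index},
        samples=dict(table.samples),
    )
    return out, log


def filter_samples(
    table: AsvTable,
    min_depth: int = 10000,
    quantile: float = 0.10,
) -> tuple[AsvTable, FilterLog]:
    """Drop shallow samples: below ``min_depth`` reads or below the
    empirical lower-``quantile`` depth of the whole dataset (type-7 /
    linear-interpolation quantile)."""
    log = FilterLog()
    depths = table.depths()
    cutoff = float(np.quantile(depths.values, quantile))
    drop = depths.index[(depths < min_depth) | (depths < cutoff)]
    log.excluded_samples = list(drop)
    log.notes.append(
        f"depth cutoff: max(min_depth={min_depth}, "
        f"q{quantile:g}={cutoff:.1f})"
    )
    keep = [s for s in table.sample_ids if s not in set(drop)]
    if not keep:
        raise ValueError("all samples excluded by depth filter")
    return table.subset_samples(keep), log


# ---------------------------------------------------------------------------
# scaling / normalisation


@dataclass
class NormalizedTable:
    """A scaled (and optionally power-transformed) ASV table.

    Lives apart from :class:`AsvTable` because its values are no longer
    raw integer counts; ``provenance`` records Cmin, the exponent, the
    seed, and the filters applied.
    """

    values: pd.DataFrame
    taxonomy: dict[str, TaxonomyLineage] = field(default_factory=dict)
    samples: dict[str, SampleMeta] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def srs_scale(
    table: AsvTable, cmin: int | None = None, seed: int = 0
) -> NormalizedTable:
    """Scale every sample to ``cmin`` total counts by ranked subsampling.

    Per sample: counts are multiplied by ``cmin/depth``; integer parts are
    kept; the remaining ``cmin - sum(integer parts)`` single counts are
    given to the ASVs with the largest fractional parts, ties broken by a
    seeded uniform draw.  Column sums equal ``cmin`` exactly for every
    seed.
    """
    depths = table.depths()
    if cmin is None:
        cmin = int(depths.min())
    if (depths < cmin).any():
        shallow = list(depths.index[depths < cmin])
        raise ValueError(f"Cmin={cmin} exceeds depth of samples {shallow}")

    out = pd.DataFrame(
        0, index=table.counts.index, columns=table.counts.columns, dtype="int64"
    )
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy(dtype=float)
        depth = col.sum()
        scaled = col * (cmin / depth)
        ints = np.floor(scaled).astype(np.int64)
        frac = scaled - ints
        remaining = int(round(cmin - ints.sum()))
        if remaining > 0:
            rng = _sample_rng(seed, sid)
            tiebreak = rng.random(len(frac))
            order = np.lexsort((tiebreak, -frac))
            ints[order[:remaining]] += 1
        out[sid] = ints
    assert (out.sum(axis=0) == cmin).all()
    return NormalizedTable(
        values=out.astype(float),
        taxonomy=dict(table.taxonomy),
        samples=dict(table.samples),
        provenance={"cmin": int(cmin), "seed": int(seed), "exponent": None},
    )


def power_transform(
    table: NormalizedTable | pd.DataFrame, exponent: float = 0.25
) -> NormalizedTable:
    """Element-wise ``x ** exponent`` (fourth root by default); 0 maps to 0."""
    values = table.values if isinstance(table, NormalizedTable) else table
    if (values.values < 0).any():
        raise ValueError("negative values cannot be power-transformed")
    transformed = values.astype(float) ** exponent
    if isinstance(table, NormalizedTable):
        prov = dict(table.provenance, exponent=exponent)
        return NormalizedTable(
            values=transformed,
            taxonomy=dict(table.taxonomy),
            samples=dict(table.samples),
            provenance=prov,
        )
    return NormalizedTable(values=transformed, provenance={"exponent": exponent})


# ---------------------------------------------------------------------------
# diversity


def _values_of(table) -> pd.DataFrame:
    if isinstance(table, AsvTable):
        return table.counts
    if isinstance(table, NormalizedTable):
        return table.values
    return table


def richness(
    table, calls: pd.Series | None = None, category: str | None = "bacteria"
) -> pd.Series:
    """Per-sample number of detected (value > 0) ASVs of a category.

    ``category=None`` counts all ASVs.
    """
    values = _values_of(table)
    if category is not None:
        if calls is None:
            raise ValueError("category richness requires classification calls")
        keep = calls.reindex(values.index) == category
        values = values.loc[keep.fillna(False)]
    return (values > 0).sum(axis=0).rename("richness")


def shannon(table) -> pd.Series:
    """Per-sample Shannon diversity H = -sum p ln p (natural log)."""
    values = _values_of(table)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero samples: {empty}")
    p = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=values.columns, name="shannon")


def bray_curtis(table) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity matrix."""
    values = _values_of(table)
    mat = ssd.squareform(ssd.pdist(values.T.values, metric="braycurtis"))
    return pd.DataFrame(mat, index=values.columns, columns=values.columns)


# ---------------------------------------------------------------------------
# sequencing-depth subsampling


def depth_profile(
    sample_counts: pd.Series,
    categories: Mapping[str, str] | pd.Series,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Category composition of a sample re-sequenced at shallower depths.

    For each requested depth, ``reps`` random subsamples of that many reads
    are drawn without replacement (multivariate hypergeometric over the
    ASV counts).  Returns, per (depth, category): the mean and sd of the
    category's read proportion and of the number of distinct ASVs of the
    category detected.  Depths exceeding the sample's depth are skipped
    with a warning.
    """
    counts = sample_counts[sample_counts > 0]
    colors = counts.to_numpy(dtype=np.int64)
    total = int(colors.sum())
    cats = pd.Series(categories).reindex(counts.index).fillna("other")
    cat_names = sorted(set(cats))
    cat_masks = {c: (cats == c).to_numpy() for c in cat_names}
    rng = np.random.default_rng(seed)

    rows = []
    for depth in depths:
        if depth > total:
            logger.warning(
                "depth %d exceeds sample depth %d; skipped", depth, total
            )
            continue
        draws = rng.multivariate_hypergeometric(
            colors, depth, size=reps, method="marginals"
        )
        for c in cat_names:
            sub = draws[:, cat_masks[c]]
            prop = sub.sum(axis=1) / depth
            distinct = (sub > 0).sum(axis=1)
            rows.append(
                {
                    "depth": depth,
                    "category": c,
                    "mean_proportion": float(prop.mean()),
                    "sd_proportion": float(prop.std(ddof=1)) if reps > 1 else 0.0,
                    "mean_distinct_asvs": float(distinct.mean()),
                    "sd_distinct_asvs": (
                        float(distinct.std(ddof=1)) if reps > 1 else 0.0
                    ),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# incidence-rate-ratio detection model


@dataclass
class IrrResult:
    """Incidence rate ratio of one bacterial family with Wald inference.

    ``irr > 1`` means the family is detected more often under treatment.
    ``separation`` marks the degenerate case where one arm has no
    detections at all: the MLE is 0 or infinite and no Wald CI exists.
    """

    family: str
    irr: float
    ci95: tuple[float, float] | None
    p: float | None
    n_pairs: int
    control_mean: float
    treated_mean: float
    separation: bool = False

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05

    def summary(self) -> str:
        ci = (
            f"[{self.ci95[0]:.3f}, {self.ci95[1]:.3f}]"
            if self.ci95
            else "[separation: no Wald CI]"
        )
        p = f"{self.p:.4g}" if self.p is not None else "n/a"
        return (
            f"IRR {self.family or '(response)'}: {self.irr:.3f} {ci}  "
            f"p={p}  arms {self.control_mean:.2f} -> {self.treated_mean:.2f}"
            f"  (n_pairs={self.n_pairs})"
        )


class DetectionIRRModel:
    """Poisson log-link GLM for per-sample detection counts.

    ``log mu_i = b0 + b1 * treated_i``; ``exp(b1)`` is the incidence rate
    ratio of the treated arm relative to control.  Fitting is by IRLS
    (deviance tolerance 1e-8, at most 100 iterations).  Build from a
    vector of counts plus treatment labels, call :meth:`fit`, read the
    :class:`IrrResult`.
    """

    SEPARATION_BETA = 30.0

    def __init__(
        self,
        counts: Sequence[float],
        treatment: Sequence,
        family: str = "",
    ) -> None:
        y = np.asarray(counts, dtype=float)
        t = np.asarray([bool(x) if isinstance(x, (bool, np.bool_)) else
                        str(x) not in {"SC-seq", "control", "0", "False"}
                        for x in treatment])
        if y.shape != t.shape:
            raise ValueError("counts and treatment labels differ in length")
        if (y < 0).any():
            raise ValueError("negative detection counts")
        if t.sum() < 2 or (~t).sum() < 2:
            raise ValueError("need at least 2 samples per arm")
        self.endog = y
        self.treated = t
        self.family_name = family

    def fit(self) -> IrrResult:
        y, t = self.endog, self.treated
        c_mean = float(y[~t].mean())
        t_mean = float(y[t].mean())
        n_pairs = int(min(t.sum(), (~t).sum()))

        if c_mean == 0 and t_mean == 0:
            raise ValueError(f"no detections in either arm ({self.family_name})")
        if c_mean == 0 or t_mean == 0:
            irr = np.inf if c_mean == 0 else 0.0
            return IrrResult(
                self.family_name, irr, None, None, n_pairs,
                c_mean, t_mean, separation=True,
            )

        exog = sm.add_constant(t.astype(float))
        res = sm.GLM(y, exog, family=sm.families.Poisson()).fit(
            tol=1e-8, maxiter=100
        )
        b1 = float(res.params[1])
        if abs(b1) > self.SEPARATION_BETA:
            irr = np.inf if b1 > 0 else 0.0
            return IrrResult(
                self.family_name, irr, None, None, n_pairs,
                c_mean, t_mean, separation=True,
            )
        lo, hi = res.conf_int()[1]
        return IrrResult(
            family=self.family_name,
            irr=float(np.exp(b1)),
            ci95=(float(np.exp(lo)), float(np.exp(hi))),
            p=float(res.pvalues[1]),
            n_pairs=n_pairs,
            control_mean=c_mean,
            treated_mean=t_mean,
        )


def fit_irr(
    family_counts_per_sample: Sequence[float],
    treatment_labels: Sequence,
    family: str = "",
) -> IrrResult:
    """Convenience wrapper around :class:`DetectionIRRModel`."""
    return DetectionIRRModel(
        family_counts_per_sample, treatment_labels, family=family
    ).fit()


def detection_counts_by_family(
    table, calls: pd.Series, rank: str = "family", response: str = "detections"
) -> pd.DataFrame:
    """Per-sample detection (or read) counts of each bacterial family.

    ``detections`` counts distinct ASVs of the family with value > 0 in
    the sample ("was the family seen, and how many of its members");
    ``reads`` sums the values instead.
    """
    values = _values_of(table)
    taxonomy = table.taxonomy
    bact = calls.reindex(values.index) == "bacteria"
    fams = pd.Series(
        {
            a: (taxonomy[a].name_at(rank) or "unannotated")
            for a in values.index
        }
    )
    values = values.loc[bact.fillna(False)]
    fams = fams.reindex(values.index)
    if response == "detections":
        return (values > 0).astype(int).groupby(fams).sum().T
    if response == "reads":
        return values.groupby(fams).sum().T
    raise ValueError(f"unknown response {response!r}")


def irr_by_family(
    table,
    calls: pd.Series,
    rank: str = "family",
    response: str = "detections",
    treated_label: str = "SCHoCO-seq",
) -> list[IrrResult]:
    """Fit the detection model for every bacterial family in the table."""
    counts = detection_counts_by_family(table, calls, rank, response)
    samples = table.samples
    treatment = [samples[s].treatment == treated_label for s in counts.index]
    results = []
    for fam in counts.columns:
        try:
            results.append(
                fit_irr(counts[fam].to_numpy(), treatment, family=fam)
            )
        except ValueError as exc:
            logger.warning("family %s skipped: %s", fam, exc)
    return results


# ---------------------------------------------------------------------------
# paired richness contrast


@dataclass
class ContrastResult:
    """Paired richness lift and Welch t-tests on category proportions."""

    lift_by_group: pd.DataFrame  # group, mean_lift_pct, n_pairs
    per_pair_lift: pd.Series  # cell_id -> (treated-control)/control
    welch: pd.DataFrame | None = None  # category, t, p, means

    @property
    def mean_lift_pct(self) -> float:
        return float(self.per_pair_lift.mean() * 100.0)


def richness_contrast(
    richness_by_sample: pd.Series,
    samples: Mapping[str, SampleMeta],
    proportions: pd.DataFrame | None = None,
    by: str = "strain",
    treated_label: str = "SCHoCO-seq",
) -> ContrastResult:
    """Per-pair relative richness increase, averaged per group.

    Each diatom cell contributes a control and a treated library sharing
    ``cell_id``; the lift is ``(treated - control) / control`` computed per
    pair and then averaged (group means of richness would understate the
    per-cell effect).  Pairs without both arms, or with zero control
    richness, are excluded with a warning.  If per-sample category
    proportions are supplied, Welch t-tests compare each category between
    arms.
    """
    pairs: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for sid, r in richness_by_sample.items():
        meta = samples[sid]
        arm = "treated" if meta.treatment == treated_label else "control"
        pairs.setdefault(meta.cell_id, {})[arm] = float(r)
        groups[meta.cell_id] = getattr(meta, by, "other")

    lifts = {}
    for cell, arms in pairs.items():
        if set(arms) != {"control", "treated"}:
            logger.warning("cell %s lacks a paired arm; excluded", cell)
            continue
        if arms["control"] == 0:
            logger.warning("cell %s has zero control richness; excluded", cell)
            continue
        lifts[cell] = (arms["treated"] - arms["control"]) / arms["control"]
    per_pair = pd.Series(lifts, name="lift")

    rows = []
    group_series = pd.Series({c: groups[c] for c in per_pair.index})
    for g, idx in group_series.groupby(group_series).groups.items():
        vals = per_pair.loc[list(idx)]
        rows.append(
            {
                "group": g,
                "mean_lift_pct": float(vals.mean() * 100.0),
                "n_pairs": len(vals),
            }
        )
    lift_by_group = pd.DataFrame(rows)

    welch = None
    if proportions is not None:
        treated_ids = [
            s for s in proportions.index
            if samples[s].treatment == treated_label
        ]
        control_ids = [
            s for s in proportions.index if s not in set(treated_ids)
        ]
        wrows = []
        for cat in proportions.columns:
            a = proportions.loc[treated_ids, cat]
            b = proportions.loc[control_ids, cat]
            t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
            wrows.append(
                {
                    "category": cat,
                    "t": float(t),
                    "p": float(p),
                    "mean_treated": float(a.mean()),
                    "sd_treated": float(a.std(ddof=1)),
                    "mean_control": float(b.mean()),
                    "sd_control": float(b.std(ddof=1)),
                }
            )
        welch = pd.DataFrame(wrows)

    return ContrastResult(
        lift_by_group=lift_by_group, per_pair_lift=per_pair, welch=welch
    )


# ---------------------------------------------------------------------------
# orchestrated run


@dataclass
class PipelineResult:
    """Bundle of everything the standard analysis produces."""

    filtered: AsvTable
    normalized: NormalizedTable
    calls: pd.Series
    proportions: pd.DataFrame
    richness: pd.Series
    shannon: pd.Series
    bray_curtis: pd.DataFrame
    asv_filter_log: FilterLog
    sample_filter_log: FilterLog


def run_pipeline(
    table: AsvTable,
    contaminants: Iterable[str] = (),
    nonmarine: Iterable[str] = (),
    min_rel: float = 0.0025,
    min_depth: int = 10000,
    depth_quantile: float = 0.10,
    cmin: int | None = None,
    exponent: float = 0.25,
    seed: int = 0,
) -> PipelineResult:
    """Filters -> depth exclusion -> SRS -> power transform -> diversity.

    Category proportions are computed on the filtered (pre-SRS) counts,
    matching how composition summaries are reported; richness, Shannon and
    Bray-Curtis use the normalised table.
    """
    filtered, asv_log = filter_asvs(
        table, min_rel=min_rel, contaminants=contaminants, nonmarine=nonmarine
    )
    filtered, sample_log = filter_samples(
        filtered, min_depth=min_depth, quantile=depth_quantile
    )
    calls = classify_asvs(filtered)
    props = category_proportions(filtered, calls)
    scaled = srs_scale(filtered, cmin=cmin, seed=seed)
    normalized = power_transform(scaled, exponent=exponent)
    rich = richness(normalized, calls, category="bacteria")
    return PipelineResult(
        filtered=filtered,
        normalized=normalized,
        calls=calls,
        proportions=props,
        richness=rich,
        shannon=shannon(normalized),
        bray_curtis=bray_curtis(normalized),
        asv_filter_log=asv_log,
        sample_filter_log=sample_log,
    )
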