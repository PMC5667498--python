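"""LTR-divergence integration dating.

A provirus integrates with identical LTR copies; each copy then accumulates
neutral substitutions independently, so the observed divergence D (in % of
sites) between aligned regions converts to an age by the molecular-clock
relation

    T = D% / r        (region vs. group consensus)
    T = D% / r / 2    (5'LTR vs. 3'LTR of the same provirus: both copies
                       accumulate mutations, hence the halving)

with r the neutral substitution rate in %/nt/My (default 0.2).  Divergence is
a p-distance with pairwise deletion (gap/N columns excluded) computed after
masking hypermutation-prone CpG dinucleotides; its dispersion is the SD of D
over bootstrap resamplings of alignment columns.  Per-locus component ages
from the different comparisons are averaged after excluding components whose
bootstrap coefficient of variation exceeds a threshold (default 0.20).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, UndefinedDistanceError
from .seqio import GAP, GappedSequence, MultipleAlignment, NucSequence

DEFAULT_RATE = 0.2  # %/nt/My, human neutral substitution rate

AGE_METHODS = [
    "ltr_vs_ltr",
    "ltr_vs_consensus",
    "gag_vs_consensus",
    "pol_vs_consensus",
    "env_vs_consensus",
]

# reference windows used for the partial-gene consensus comparisons
POL_DATING_WINDOW = (1277, 2571)
ENV_DATING_WINDOW = (4103, 5810)


def round1(x: float) -> float:
    """Round half-up to 1 decimal (table-reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _residues(x) -> str:
    if isinstance(x, (NucSequence, GappedSequence)):
        return x.residues
    return str(x).upper()


@dataclass(frozen=True)
class DivergenceEstimate:
    """One D% measurement: comparison method, region, sites used after
    pairwise deletion/CpG masking, and bootstrap dispersion."""

    method: str
    region_label: str
    d_percent: float
    sites_used: int
    bootstrap_sd: float = 0.0
    n_boot: int = 0

    def __post_init__(self):
        if not (0 <= self.d_percent <= 100):
            raise InputError("d_percent must be within [0, 100]")


@dataclass
class AgeEstimate:
    """Aggregate per-locus age: retained component ages and their mean."""

    locus: str
    component_ages: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)
    final_t_my: float | None = None
    undatable: bool = False


# ---------------------------------------------------------------------------
# consensus, masking, distance
# ---------------------------------------------------------------------------


def majority_consensus(msa: MultipleAlignment, seq_id: str = "consensus") -> NucSequence:
    """Majority-rule consensus of an alignment.

    Per column the most frequent symbol among {A,C,G,T,-} wins (N never
    wins); gap-majority columns are dropped, so the consensus is ungapped.
    Ties break alphabetically (A<C<G<T), letters beating the gap.
    """
    if not isinstance(msa, MultipleAlignment):
        raise InputError("majority_consensus expects a MultipleAlignment")
    mat = msa.to_matrix()
    out = []
    order = "ACGT-"  # tie-break order; gap last so letters win ties
    for col in mat.T:
        counts = {c: int(np.count_nonzero(col == i)) for i, c in enumerate("ACGTN")}
        counts[GAP] = int(np.count_nonzero(col == 5))
        best = max(order, key=lambda c: (counts[c], -order.index(c)))
        if best != GAP and counts[best] > 0:
            out.append(best)
        elif best == GAP:
            continue
    if not out:
        raise InputError("alignment yields an empty consensus")
    return NucSequence(seq_id, "".join(out))


def mask_cpg_sites(gapped_a, gapped_b) -> tuple[str, str]:
    """Mask hypermutation-prone CpG dinucleotides with N in both rows.

    A CpG is a C followed by a G in either sequence, adjacency being judged on
    the non-gap residues of that sequence (gap columns in between are ignored
    when locating the neighbour).  Both alignment columns of every such
    dinucleotide are masked in both rows.
    """
    a, b = _residues(gapped_a), _residues(gapped_b)
    if len(a) != len(b):
        raise InputError("rows must have equal (aligned) length")
    masked = set()
    for row in (a, b):
        idx = [i for i, c in enumerate(row) if c != GAP]
        for k in range(len(idx) - 1):
            i, j = idx[k], idx[k + 1]
            if row[i] == "C" and row[j] == "G":
                masked.add(i)
                masked.add(j)

    def apply(row: str) -> str:
        return "".join(
            "N" if (i in masked and c != GAP) else c for i, c in enumerate(row)
        )

    return apply(a), apply(b)


def p_distance(gapped_a, gapped_b) -> tuple[float, int]:
    """Percent divergent sites under pairwise deletion.

    Columns where either row holds a gap or N are excluded; returns
    ``(D%, sites_used)``.
    """
    a, b = _residues(gapped_a), _residues(gapped_b)
    if len(a) != len(b):
        raise InputError("rows must have equal (aligned) length")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    bad = np.isin(aa, [ord(GAP), ord("N")]) | np.isin(bb, [ord(GAP), ord("N")])
    use = ~bad
    sites = int(use.sum())
    if sites == 0:
        raise UndefinedDistanceError("no usable sites after pairwise deletion")
    mism = int(np.count_nonzero(aa[use] != bb[use]))
    return 100.0 * mism / sites, sites


def bootstrap_divergence(gapped_a, gapped_b, n: int = 1000, seed: int | None = None) -> float:
    """SD of D% over ``n`` column-bootstrap replicates (pairwise deletion is
    reapplied within each replicate). Deterministic under a fixed seed."""
    a, b = _residues(gapped_a), _residues(gapped_b)
    if len(a) != len(b):
        raise InputError("rows must have equal (aligned) length")
    if n < 2:
        raise InputError("need n >= 2 bootstrap replicates")
    p_distance(a, b)  # raises UndefinedDistanceError on degenerate pairs
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    usable = ~(np.isin(aa, [ord(GAP), ord("N")]) | np.isin(bb, [ord(GAP), ord("N")]))
    mism = (aa != bb) & usable
    rng = np.random.default_rng(seed)
    L = len(a)
    ds = []
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        u = usable[idx]
        s = int(u.sum())
        if s == 0:
            continue
        ds.append(100.0 * int(mism[idx].sum()) / s)
    if not ds:
        raise UndefinedDistanceError("all bootstrap replicates degenerate")
    return float(np.std(ds, ddof=0))


def estimate_divergence(
    gapped_a,
    gapped_b,
    method: str,
    region_label: str,
    *,
    mask_cpg: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DivergenceEstimate:
    """Measure D% between two aligned rows with the full protocol: optional
    CpG masking, pairwise deletion, column-bootstrap dispersion."""
    a, b = _residues(gapped_a), _residues(gapped_b)
    if mask_cpg:
        a, b = mask_cpg_sites(a, b)
    d, sites = p_distance(a, b)
    sd = bootstrap_divergence(a, b, n=n_boot, seed=seed) if n_boot >= 2 else 0.0
    return DivergenceEstimate(
        method=method,
        region_label=region_label,
        d_percent=d,
        sites_used=sites,
        bootstrap_sd=sd,
        n_boot=max(n_boot, 0),
    )


# ---------------------------------------------------------------------------
# age estimators
# ---------------------------------------------------------------------------


def age_from_ltr_pair(d_percent: float, rate: float = DEFAULT_RATE, halve: bool = True) -> float:
    """Age from inter-LTR divergence: T = D%/rate, halved because both LTR
    copies accumulate substitutions independently."""
    if rate <= 0:
        raise ConfigError("rate must be > 0")
    if d_percent < 0:
        raise InputError("d_percent must be >= 0")
    t = d_percent / rate
    return t / 2.0 if halve else t


def age_from_consensus(d_percent: float, rate: float = DEFAULT_RATE) -> float:
    """Age from divergence to the group consensus: T = D%/rate."""
    if rate <= 0:
        raise ConfigError("rate must be > 0")
    if d_percent < 0:
        raise InputError("d_percent must be >= 0")
    return d_percent / rate


def age_for_estimate(
    est: DivergenceEstimate, rate: float = DEFAULT_RATE, halve_ltr: bool = True
) -> float:
    if est.method == "ltr_vs_ltr":
        return age_from_ltr_pair(est.d_percent, rate, halve=halve_ltr)
    return age_from_consensus(est.d_percent, rate)


def aggregate_component_ages(
    locus: str,
    component_ages: dict[str, float],
    excluded: dict[str, str] | None = None,
) -> AgeEstimate:
    """Mean of retained component ages, reported to 1 decimal."""
    excluded = dict(excluded or {})
    retained = {k: v for k, v in component_ages.items() if k not in excluded}
    if not retained:
        return AgeEstimate(locus, component_ages, excluded, None, undatable=True)
    final = round1(float(np.mean(list(retained.values()))))
    return AgeEstimate(locus, component_ages, excluded, final)


def aggregate_locus_age(
    estimates: list[DivergenceEstimate],
    *,
    locus: str = "",
    rate: float = DEFAULT_RATE,
    cv_threshold: float = 0.20,
    halve_ltr: bool = True,
    outlier_regions: set[str] | None = None,
) -> AgeEstimate:
    """Convert divergence estimates to component ages and aggregate.

    A component is excluded when its bootstrap coefficient of variation
    (bootstrap SD of D over D) exceeds ``cv_threshold``, or when its region is
    flagged as an outlier.  All components excluded yields an undatable flag,
    not an error.
    """
    if not estimates:
        raise InputError("need at least one divergence estimate")
    ages, excluded = {}, {}
    for est in estimates:
        key = est.method if est.method != "gene_vs_consensus" else f"{est.region_label}_vs_consensus"
        ages[key] = age_for_estimate(est, rate, halve_ltr)
        if outlier_regions and est.region_label in outlier_regions:
            excluded[key] = "flagged outlier"
        elif est.d_percent > 0 and est.n_boot >= 2 and est.bootstrap_sd / est.d_percent > cv_threshold:
            excluded[key] = (
                f"bootstrap CV {est.bootstrap_sd / est.d_percent:.2f} > {cv_threshold:.2f}"
            )
    return aggregate_component_ages(locus, ages, excluded)


# ---------------------------------------------------------------------------
# age-table summary
# ---------------------------------------------------------------------------


@dataclass
class AgeTableSummary:
    """Table-shaped dating results: one row per locus, one column per method,
    an Average column, per-method column means and implied divergences."""

    table: pd.DataFrame
    column_means: dict[str, float]
    implied_divergence: dict[str, float]
    rate: float

    def summary(self) -> pd.DataFrame:
        frame = self.table.copy()
        means = {m: self.column_means.get(m) for m in frame.columns}
        frame.loc["Average"] = pd.Series(means)
        return frame


def summarize_age_table(
    age_estimates: list[AgeEstimate], rate: float = DEFAULT_RATE
) -> AgeTableSummary:
    """Column means over loci possessing each component (1 decimal), plus the
    implied mean divergence per method (mean T x rate)."""
    if not age_estimates:
        raise InputError("no age estimates")
    rows = {}
    for est in age_estimates:
        row = {m: est.component_ages.get(m) for m in AGE_METHODS}
        row["Average"] = est.final_t_my
        rows[est.locus] = row
    table = pd.DataFrame.from_dict(rows, orient="index")

    column_means, implied = {}, {}
    for method in AGE_METHODS + ["Average"]:
        vals = []
        for est in age_estimates:
            if method == "Average":
                if est.final_t_my is not None:
                    vals.append(est.final_t_my)
                continue
            if method in est.component_ages and method not in est.excluded:
                vals.append(est.component_ages[method])
        if vals:
            mean_t = float(np.mean(vals))
            column_means[method] = round1(mean_t)
            if method != "Average":
                implied[method] = round1(mean_t * rate)
    return AgeTableSummary(table, column_means, implied, rate)


def age_table_from_components(components: pd.DataFrame) -> list[AgeEstimate]:
    """Build per-locus aggregates from a (locus, method, t_my, excluded, note)
    component table (the packaged published-table fixture has this shape)."""
    out = []
    for locus, grp in components.groupby("locus", sort=False):
        ages = dict(zip(grp["method"], grp["t_my"].astype(float)))
        excluded = {
            m: (n or "excluded")
            for m, n, x in zip(grp["method"], grp.get("note", ""), grp["excluded"])
            if bool(x)
        }
        out.append(aggregate_component_ages(str(locus), ages, excluded))
    return out
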