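"""Chromosomal-distribution statistics for integration events.

Under random integration the expected count on chromosome c is proportional
to its length: E_c = L_c * N / sum(L).  The overall departure from this model
is a chi-square test over chromosomes; per-chromosome departures are 1-df
chi-square tests on the two-cell partition {c, all others}.  Solo LTRs and
proviruses count as equal integration events; duplicated loci sharing one
ancestral integration can be collapsed beforehand.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    excluded: list[str]


@dataclass
class ChromosomeCounts:
    """Per-chromosome observed/expected table plus the overall test."""

    table: pd.DataFrame  # chrom, length_bp, observed, expected, fold, p_value
    overall: ChiSquareResult
    mean_per_chrom_p: float


def expected_counts(chrom_lengths, total_insertions: int | float) -> pd.Series:
    """Length-proportional expected counts: E_c = L_c * N / sum(L)."""
    lengths = pd.Series(dict(chrom_lengths), dtype=float)
    if lengths.empty:
        raise InputError("empty chromosome length table")
    if (lengths <= 0).any():
        raise InputError("chromosome lengths must be positive")
    if total_insertions < 0:
        raise InputError("total insertions must be >= 0")
    return lengths * float(total_insertions) / float(lengths.sum())


def overall_chi_square(observed, expected) -> ChiSquareResult:
    """X^2 = sum (O-E)^2/E over chromosomes, df = k-1, upper-tail p.

    Chromosomes with E = 0 are excluded with a warning (df adjusted).
    """
    obs = pd.Series(dict(observed), dtype=float)
    exp = pd.Series(dict(expected), dtype=float)
    if set(obs.index) != set(exp.index):
        raise InputError("observed and expected must cover the same chromosomes")
    exp = exp.reindex(obs.index)
    excluded = list(obs.index[exp == 0])
    if excluded:
        warnings.warn(f"chromosomes with zero expectation excluded: {excluded}")
        keep = exp > 0
        obs, exp = obs[keep], exp[keep]
    if len(obs) < 2:
        raise InputError("need at least 2 chromosomes with positive expectation")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p, excluded)


def per_chromosome_tests(observed, expected, bonferroni: bool = False) -> tuple[pd.Series, float]:
    """1-df chi-square per chromosome on the {c, rest} two-cell partition.

    Returns the per-chromosome p-values (optionally Bonferroni-adjusted) and
    their mean.
    """
    obs = pd.Series(dict(observed), dtype=float)
    exp = pd.Series(dict(expected), dtype=float)
    if set(obs.index) != set(exp.index):
        raise InputError("observed and expected must cover the same chromosomes")
    exp = exp.reindex(obs.index)
    N = obs.sum()
    ps = {}
    for c in obs.index:
        e_c, o_c = exp[c], obs[c]
        if e_c <= 0 or N - e_c <= 0:
            warnings.warn(f"chromosome {c} skipped (zero expectation cell)")
            continue
        stat = (o_c - e_c) ** 2 / e_c + ((N - o_c) - (N - e_c)) ** 2 / (N - e_c)
        p = float(stats.chi2.sf(stat, 1))
        ps[c] = min(1.0, p * len(obs)) if bonferroni else p
    if not ps:
        raise InputError("no testable chromosomes")
    series = pd.Series(ps)
    return series, float(series.mean())


def count_insertions(locus_table, chrom_lengths, collapse: dict[str, str] | None = None) -> pd.Series:
    """Observed integration events per chromosome from a locus table.

    ``collapse`` maps locus names to a shared integration identifier so that
    duplicated proviruses from one ancestral event count once.
    """
    if hasattr(locus_table, "itertuples"):
        frame = locus_table
    else:  # list of ProviralLocus
        frame = pd.DataFrame(
            [{"name": l.name, "chrom": l.chrom} for l in locus_table]
        )
    if frame.empty:
        raise InputError("empty locus table")
    frame = frame.copy()
    if collapse:
        frame["event"] = [collapse.get(n, n) for n in frame["name"]]
        frame = frame.drop_duplicates("event")
    lengths = pd.Series(dict(chrom_lengths), dtype=float)
    counts = frame["chrom"].astype(str).value_counts()
    return counts.reindex(lengths.index.astype(str), fill_value=0).astype(int)


def distribution_report(
    locus_table,
    chrom_lengths,
    collapse: dict[str, str] | None = None,
    bonferroni: bool = False,
) -> ChromosomeCounts:
    """Full distribution analysis: counts, expectations, folds, overall and
    per-chromosome tests."""
    lengths = pd.Series(dict(chrom_lengths), dtype=float)
    observed = count_insertions(locus_table, lengths, collapse)
    expected = expected_counts(lengths, int(observed.sum()))
    overall = overall_chi_square(observed, expected)
    per_p, mean_p = per_chromosome_tests(observed, expected, bonferroni)
    table = pd.DataFrame(
        {
            "chrom": lengths.index.astype(str),
            "length_bp": lengths.values,
            "observed": observed.values,
            "expected": expected.values,
        }
    )
    table["fold"] = np.where(table["expected"] > 0, table["observed"] / table["expected"], np.nan)
    table["p_value"] = [per_p.get(c, np.nan) for c in table["chrom"]]
    return ChromosomeCounts(table=table, overall=overall, mean_per_chrom_p=mean_p)
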