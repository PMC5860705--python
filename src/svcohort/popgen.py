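"""Allele frequencies and marker-diversity statistics.

For a biallelic insertion/deletion site genotyped as II / ID / DD, the
allele frequencies follow from gene counting, and the standard marker
statistics from the frequency vector p:

    Ho  = sum p_i^2            (gene homozygosity)
    He  = 1 - Ho               (expected heterozygosity)
    Ne  = 1 / sum p_i^2        (effective number of alleles)
    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

Between-population genotype-frequency differences are tested with a
Pearson chi-square on the population x genotype table, falling back to
Fisher's exact test on the DD-vs-rest collapse when any expected cell is
below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sv_io import GenotypeTable

GENOTYPE_CLASSES = ("II", "ID", "DD")


def allele_frequencies(counts: Mapping[str, int]) -> tuple[float, float]:
    """(p_I, p_D) by gene counting from II/ID/DD genotype counts."""
    n_ii = int(counts.get("II", 0))
    n_id = int(counts.get("ID", 0))
    n_dd = int(counts.get("DD", 0))
    if min(n_ii, n_id, n_dd) < 0:
        raise ValueError("negative genotype count")
    n = n_ii + n_id + n_dd
    if n == 0:
        raise ValueError("no genotyped individuals")
    p_i = (2 * n_ii + n_id) / (2 * n)
    return p_i, 1.0 - p_i


@dataclass(frozen=True)
class DiversityStats:
    ho: float   # gene homozygosity, sum p^2
    he: float   # expected heterozygosity, 1 - Ho
    ne: float   # effective allele number, 1 / Ho
    pic: float  # polymorphism information content


def diversity_stats(freqs: Sequence[float], tol: float = 1e-9) -> DiversityStats:
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    ho = float((p ** 2).sum())
    he = 1.0 - ho
    ne = 1.0 / ho
    sq = p ** 2
    # sum over unordered pairs of 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pair_term = float(sq.sum() ** 2 - (sq ** 2).sum())
    pic = 1.0 - ho - pair_term
    return DiversityStats(ho=ho, he=he, ne=ne, pic=pic)


@dataclass(frozen=True)
class FreqTestResult:
    statistic: float
    p: float
    method: str  # "chi2" or "fisher"


def genotype_freq_test(counts_a: Mapping[str, int],
                       counts_b: Mapping[str, int]) -> FreqTestResult:
    """Compare genotype-class distributions between two populations.

    Classes absent from both populations are dropped before testing.  If
    any expected cell of the chi-square falls below 5, the table is
    collapsed to DD vs not-DD and Fisher's exact test reported instead.
    """
    table = np.array([[counts_a.get(g, 0) for g in GENOTYPE_CLASSES],
                      [counts_b.get(g, 0) for g in GENOTYPE_CLASSES]], dtype=int)
    if table.sum(axis=1).min() == 0:
        raise ValueError("a population has no genotyped individuals")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        # only one genotype class present anywhere: no difference testable
        return FreqTestResult(statistic=0.0, p=1.0, method="degenerate")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq >= 5).all():
        return FreqTestResult(float(res.statistic), float(res.pvalue), "chi2")
    dd_a = counts_a.get("DD", 0)
    dd_b = counts_b.get("DD", 0)
    rest_a = sum(counts_a.get(g, 0) for g in ("II", "ID"))
    rest_b = sum(counts_b.get(g, 0) for g in ("II", "ID"))
    odds, p = stats.fisher_exact([[dd_a, rest_a], [dd_b, rest_b]])
    return FreqTestResult(float(odds), float(p), "fisher")


def locus_stats_table(gt: GenotypeTable) -> pd.DataFrame:
    """Per (locus, population): allele frequencies and diversity stats."""
    rows = []
    for rec in gt.table.itertuples():
        counts = {"II": rec.n_II, "ID": rec.n_ID, "DD": rec.n_DD}
        p_i, p_d = allele_frequencies(counts)
        d = diversity_stats([p_i, p_d])
        rows.append({"locus_id": rec.locus_id, "population_id": rec.population_id,
                     "n": sum(counts.values()), "p_I": p_i, "p_D": p_d,
                     "Ho": d.ho, "He": d.he, "Ne": d.ne, "PIC": d.pic})
    return pd.DataFrame(rows)


def pairwise_freq_tests(gt: GenotypeTable) -> pd.DataFrame:
    """All within-locus population pairs, with test statistic, p and path."""
    rows = []
    for locus, grp in gt.table.groupby("locus_id"):
        pops = list(grp.population_id)
        recs = {r.population_id: {"II": r.n_II, "ID": r.n_ID, "DD": r.n_DD}
                for r in grp.itertuples()}
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                res = genotype_freq_test(recs[a], recs[b])
                rows.append({"locus_id": locus, "pop_a": a, "pop_b": b,
                             "statistic": res.statistic, "p": res.p,
                             "method": res.method})
    return pd.DataFrame(rows)
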