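"""Gene-model annotation of population SVs and downstream statistics.

Each SV is classified against every gene it touches with the precedence
exonic (any CDS overlap) > UTR > intronic; an SV touching no gene body but
lying within a configurable flank (5 kb by default) of one is upstream or
downstream of it by strand, and anything else is intergenic.  Exonic and
UTR hits are flagged loss-of-function (LoF).  On top of the per-gene
records the module computes the conserved-gene depletion chi-square, the
Spearman correlation between per-gene SV count and transcript count, and
a sliding-window hotspot scan of SV density.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .popmerge import PopulationSv
from .sv_io import Gene, GeneSet, chrom_sort_key

DEFAULT_FLANK_BP = 5000

# per-SV summary keeps the most severe class only
CLASS_PRECEDENCE = ("exonic", "utr", "intronic", "upstream", "downstream",
                    "intergenic")
LOF_CLASSES = frozenset({"exonic", "utr"})


@dataclass(frozen=True)
class Consequence:
    sv_id: str
    gene_id: str          # "" for intergenic
    consequence: str      # one of CLASS_PRECEDENCE
    lof: bool


class GeneIndex:
    """Interval lookup of gene bodies (and flanks) per chromosome."""

    def __init__(self, genes: GeneSet, flank_bp: int = DEFAULT_FLANK_BP):
        self.flank_bp = flank_bp
        self.body: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.flanked: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self.body[g.chrom][g.start:g.end] = g
            self.flanked[g.chrom][max(0, g.start - flank_bp):g.end + flank_bp] = g

    def overlapping(self, chrom, start, end) -> list[Gene]:
        return [iv.data for iv in self.body.get(chrom, IntervalTree())
                .overlap(start, end)]

    def nearby(self, chrom, start, end) -> list[Gene]:
        return [iv.data for iv in self.flanked.get(chrom, IntervalTree())
                .overlap(start, end)]


def _query_span(sv: PopulationSv) -> tuple[int, int]:
    # insertions are zero-width; query the single breakpoint base
    if sv.start == sv.end:
        return sv.start, sv.start + 1
    return sv.start, sv.end


def _gene_class(sv_start: int, sv_end: int, gene: Gene) -> str:
    for t in gene.transcripts:
        for s, e in t.cds:
            if min(e, sv_end) > max(s, sv_start):
                return "exonic"
    for t in gene.transcripts:
        for s, e in t.utrs:
            if min(e, sv_end) > max(s, sv_start):
                return "utr"
    return "intronic"


def classify_sv(sv: PopulationSv, genes: GeneSet | GeneIndex,
                flank_bp: int = DEFAULT_FLANK_BP) -> list[Consequence]:
    """One record per overlapped gene; flank records when nothing is hit;
    a single intergenic record otherwise."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, flank_bp)
    qs, qe = _query_span(sv)
    hits = index.overlapping(sv.chrom, qs, qe)
    if hits:
        out = []
        for g in sorted(hits, key=lambda g: g.gene_id):
            cls = _gene_class(qs, qe, g)
            out.append(Consequence(sv.sv_id, g.gene_id, cls, cls in LOF_CLASSES))
        return out
    near = index.nearby(sv.chrom, qs, qe)
    if near:
        out = []
        for g in sorted(near, key=lambda g: g.gene_id):
            # before the gene start on the + strand means upstream;
            # strand flips the sense
            before = qe <= g.start
            if g.strand == "+":
                cls = "upstream" if before else "downstream"
            else:
                cls = "downstream" if before else "upstream"
            out.append(Consequence(sv.sv_id, g.gene_id, cls, False))
        return out
    return [Consequence(sv.sv_id, "", "intergenic", False)]


def annotate_callset(callset: Sequence[PopulationSv], genes: GeneSet,
                     flank_bp: int = DEFAULT_FLANK_BP) -> list[Consequence]:
    index = GeneIndex(genes, flank_bp)
    out: list[Consequence] = []
    for sv in callset:
        out.extend(classify_sv(sv, index, flank_bp))
    return out


def consequences_to_frame(consequences: Sequence[Consequence]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in consequences],
                        columns=["sv_id", "gene_id", "consequence", "lof"])


def sv_class_summary(consequences: Sequence[Consequence]) -> pd.Series:
    """Most severe class per SV (one entry per SV id)."""
    rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    best: dict[str, str] = {}
    for c in consequences:
        cur = best.get(c.sv_id)
        if cur is None or rank[c.consequence] < rank[cur]:
            best[c.sv_id] = c.consequence
    return pd.Series(best, name="consequence")


def consequence_summary(consequences: Sequence[Consequence]) -> pd.DataFrame:
    """Counts and fractions per class; each SV counted once at its most
    severe class, so fractions sum to 1 over the partition."""
    per_sv = sv_class_summary(consequences)
    counts = per_sv.value_counts().reindex(CLASS_PRECEDENCE, fill_value=0)
    frac = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame({"count": counts, "fraction": frac})


def lof_catalog(consequences: Sequence[Consequence]) -> pd.DataFrame:
    """All (SV, gene) records flagged loss-of-function."""
    df = consequences_to_frame(consequences)
    return df[df.lof].reset_index(drop=True)


def gene_sv_table(consequences: Sequence[Consequence],
                  genes: GeneSet) -> pd.DataFrame:
    """Per gene: number of distinct SVs overlapping or nearby, transcript
    count and conserved flag.  Genes untouched by any SV have sv_count 0."""
    per_gene: dict[str, set[str]] = defaultdict(set)
    for c in consequences:
        if c.gene_id:
            per_gene[c.gene_id].add(c.sv_id)
    rows = []
    for g in genes:
        rows.append({"gene_id": g.gene_id,
                     "sv_count": len(per_gene.get(g.gene_id, ())),
                     "transcript_count": g.transcript_count,
                     "conserved": g.conserved})
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class Chi2Result:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p: float


def conserved_gene_test(n_conserved_with_sv: int, n_conserved_total: int,
                        n_genes_with_sv: int, n_genes_total: int) -> Chi2Result:
    """Pearson chi-square (no continuity correction) for SV depletion in
    conserved genes.

    The 2x2 table is (conserved, other) x (with SV, without SV), where the
    "other" row is the complement of the conserved row within the genome
    totals.
    """
    if not (0 <= n_conserved_with_sv <= n_conserved_total):
        raise ValueError("conserved with-SV count exceeds total")
    if not (0 <= n_genes_with_sv <= n_genes_total):
        raise ValueError("with-SV count exceeds total")
    obs = np.array([
        [n_conserved_with_sv, n_conserved_total - n_conserved_with_sv],
        [n_genes_with_sv - n_conserved_with_sv,
         (n_genes_total - n_conserved_total) - (n_genes_with_sv - n_conserved_with_sv)],
    ], dtype=float)
    if (obs < 0).any():
        raise ValueError("inconsistent marginals")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq == 0).any():
        raise ValueError("degenerate table: zero expected cell")
    return Chi2Result(observed=obs, expected=res.expected_freq,
                      statistic=float(res.statistic), df=1, p=float(res.pvalue))


def transcript_correlation(table: pd.DataFrame,
                           sv_bearing_only: bool = False) -> tuple[float, float]:
    """Spearman rank correlation between per-gene SV count and transcript
    count (average ranks for ties, t-approximation p-value).

    Returns (nan, nan) when either variable has zero variance.
    """
    df = table
    if sv_bearing_only:
        df = df[df.sv_count > 0]
    if len(df) < 3:
        raise ValueError("need at least 3 genes")
    x = df["sv_count"].to_numpy(float)
    y = df["transcript_count"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class HotspotWindow:
    chrom: str
    start: int
    end: int
    sv_count: int
    z: float


def window_counts(callset: Sequence[PopulationSv],
                  chrom_lengths: Mapping[str, int],
                  window_bp: int = 1_000_000,
                  step_bp: int = 500_000) -> pd.DataFrame:
    """SV start positions tallied per sliding window over all chromosomes."""
    if window_bp <= 0 or step_bp <= 0 or step_bp > window_bp:
        raise ValueError("need 0 < step_bp <= window_bp")
    missing = {sv.chrom for sv in callset} - set(chrom_lengths)
    if missing:
        raise ValueError(f"chromosome lengths missing for: {sorted(missing)}")
    starts_by_chrom: dict[str, list[int]] = defaultdict(list)
    for sv in callset:
        starts_by_chrom[sv.chrom].append(sv.start)
    rows = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        positions = np.sort(np.asarray(starts_by_chrom.get(chrom, []), dtype=int))
        length = int(chrom_lengths[chrom])
        w0 = 0
        while w0 < length:
            w1 = min(w0 + window_bp, length)
            n = int(np.searchsorted(positions, w1, "left")
                    - np.searchsorted(positions, w0, "left"))
            rows.append({"chrom": chrom, "start": w0, "end": w1, "sv_count": n})
            if w0 + window_bp >= length:
                break
            w0 += step_bp
    return pd.DataFrame(rows)


def hotspot_scan(callset: Sequence[PopulationSv],
                 chrom_lengths: Mapping[str, int],
                 window_bp: int = 1_000_000,
                 step_bp: int = 500_000,
                 z_threshold: float = 3.0) -> list[HotspotWindow]:
    """Sliding-window density scan with a robust, multiplicity-controlled
    background test.

    The background rate is the median window count — robust, unlike the
    mean/SD, to contamination by the hotspot itself when it spans a
    non-negligible fraction of the genome.  Each window's reported z is
    its count standardised by the Poisson spread sqrt(median); a window is
    called hot when its Poisson upper-tail probability under the
    background rate is below the normal tail mass of ``z_threshold``
    divided by the number of windows (Bonferroni), so the family-wise
    false-hotspot rate over the whole scan is held near
    ``P(Z >= z_threshold)`` rather than growing with genome size.
    Overlapping hot windows merge (per chromosome) into maximal intervals.
    """
    wins = window_counts(callset, chrom_lengths, window_bp, step_bp)
    if wins.empty or wins.sv_count.sum() == 0:
        return []
    lam = max(float(wins.sv_count.median()), 1.0)
    alpha = float(stats.norm.sf(z_threshold)) / len(wins)
    wins = wins.assign(z=(wins.sv_count - lam) / np.sqrt(lam))
    hot = wins[stats.poisson.sf(wins.sv_count - 1, lam) < alpha]
    out: list[HotspotWindow] = []
    for chrom, grp in hot.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_z = 0.0
        merged = []
        for row in grp.itertuples():
            if cur_start is None or row.start > cur_end:
                if cur_start is not None:
                    merged.append((cur_start, cur_end, cur_z))
                cur_start, cur_end, cur_z = row.start, row.end, row.z
            else:
                cur_end = max(cur_end, row.end)
                cur_z = max(cur_z, row.z)
        if cur_start is not None:
            merged.append((cur_start, cur_end, cur_z))
        for s, e, z in merged:
            n = sum(1 for sv in callset if sv.chrom == chrom and s <= sv.start < e)
            out.append(HotspotWindow(chrom, int(s), int(e), n, float(z)))
    out.sort(key=lambda h: (chrom_sort_key(h.chrom), h.start))
    return out


def hotspots_to_bed(hotspots: Sequence[HotspotWindow], path) -> None:
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t"
                     f"sv_count={h.sv_count};z={h.z:.3f}\n")
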