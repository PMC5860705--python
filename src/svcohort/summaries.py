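"""Descriptive tables over the cohort call set.

Length-bin tables (50-1000 bp / 1-10 kb / 10-100 kb, bounds inclusive),
type composition, per-chromosome counts and densities, covered genome
length (both the naive per-type length sum and the interval union, which
differ whenever records overlap), and sequencing-QC column aggregates.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import pandas as pd

from .sv_io import SV_TYPES, chrom_sort_key

DEFAULT_BINS = ((50, 1000), (1001, 10_000), (10_001, 100_000))
BIN_LABELS = ("50-1000 bp", "1-10 kb", "10-100 kb", ">100 kb")


def length_bin_table(callset: Sequence,
                     bins: Sequence[tuple[int, int]] = DEFAULT_BINS) -> pd.DataFrame:
    """Count and total length per SV type per closed length bin, with an
    overflow row for anything beyond the last bin."""
    labels = [f"{lo}-{hi}" if (lo, hi) not in DEFAULT_BINS else BIN_LABELS[i]
              for i, (lo, hi) in enumerate(bins)]
    overflow = f">{bins[-1][1]}"
    counts = {t: defaultdict(int) for t in SV_TYPES}
    lengths = {t: defaultdict(int) for t in SV_TYPES}
    for sv in callset:
        label = overflow
        for (lo, hi), lab in zip(bins, labels):
            if lo <= sv.length <= hi:
                label = lab
                break
        counts[sv.sv_type][label] += 1
        lengths[sv.sv_type][label] += sv.length
    rows = []
    for lab in [*labels, overflow]:
        row = {"bin": lab}
        for t in SV_TYPES:
            row[f"{t}_N"] = counts[t][lab]
            row[f"{t}_L"] = lengths[t][lab]
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def type_composition(callset_or_counts) -> pd.DataFrame:
    """Per-type count and percentage of the total (2 dp).

    Accepts either a call-set sequence or a ready {type: count} mapping,
    so published count tables can be fed through the same arithmetic.
    """
    if isinstance(callset_or_counts, Mapping):
        counts = dict(callset_or_counts)
    else:
        counts = defaultdict(int)
        for sv in callset_or_counts:
            counts[sv.sv_type] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty callset")
    rows = [{"sv_type": t, "count": counts.get(t, 0),
             "percent": round(100.0 * counts.get(t, 0) / total, 2)}
            for t in SV_TYPES if counts.get(t, 0) or t in counts]
    return pd.DataFrame(rows).set_index("sv_type")


def chromosome_distribution(callset: Sequence,
                            chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-chromosome SV count, fraction of the total (%) and density
    (SVs per Mb of chromosome length)."""
    counts = defaultdict(int)
    for sv in callset:
        if sv.chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {sv.chrom!r}")
        counts[sv.chrom] += 1
    total = sum(counts.values())
    rows = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        n = counts.get(chrom, 0)
        mb = chrom_lengths[chrom] / 1e6
        rows.append({"chrom": chrom, "count": n,
                     "fraction_pct": 100.0 * n / total if total else 0.0,
                     "density_per_mb": n / mb})
    return pd.DataFrame(rows).set_index("chrom")


def covered_length(callset: Sequence) -> dict:
    """Genome length affected by the call set.

    ``sum_bp`` adds every record's length (insertions contribute their
    inserted length); ``union_bp`` counts reference bases covered by at
    least one interval, so insertions (zero reference width) contribute
    nothing and overlapping records are counted once.  Both are reported
    because they genuinely differ.
    """
    sums = defaultdict(int)
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for sv in callset:
        sums[sv.sv_type] += sv.length
        if sv.end > sv.start:
            by_chrom[sv.chrom].append((sv.start, sv.end))
    union = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                union += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        union += cur_e - cur_s
    return {"sum_bp_by_type": dict(sums),
            "sum_bp": int(sum(sums.values())),
            "union_bp": int(union)}


SEQ_SUMMARY_COLUMNS = ("raw_gb", "clean_gb", "mapped_gb", "map_ratio_pct",
                       "depth_x", "q20_pct", "gc_pct")


def sequencing_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Column sums and means (2 dp) of a per-sample sequencing QC table."""
    if len(table) == 0:
        raise ValueError("empty sequencing summary table")
    cols = [c for c in SEQ_SUMMARY_COLUMNS if c in table.columns]
    agg = pd.DataFrame({"total": table[cols].sum(), "mean": table[cols].mean()})
    return agg.round(2)
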