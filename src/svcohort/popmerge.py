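"""Cross-individual merging into a non-redundant population call set.

Per-sample consensus SVs from the whole cohort are pooled and clustered
with the same 25 bp / same-type / same-chromosome rule used within
samples.  Clusters carried by fewer than ``min_individuals`` distinct
samples (two, by default) are discarded; each surviving cluster becomes
one population SV with a zero-padded serial ID assigned in (chrom, start)
order, its carrier set, and the breeds/groups those carriers belong to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import (DEFAULT_INS_WINDOW, DEFAULT_MIN_OVERLAP, ConsensusSv,
                        cluster_calls)
from .sv_io import SampleSheet, chrom_sort_key

DEFAULT_MIN_INDIVIDUALS = 2


@dataclass(frozen=True)
class PopulationSv:
    sv_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    carriers: frozenset[str]
    breeds: frozenset[str] = frozenset()
    groups: frozenset[str] = frozenset()
    truth_ids: frozenset[str] = frozenset()

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def merge_across_samples(per_sample: Mapping[str, Sequence[ConsensusSv]],
                         sample_sheet: SampleSheet | None = None,
                         min_overlap: int = DEFAULT_MIN_OVERLAP,
                         ins_window: int = DEFAULT_INS_WINDOW,
                         min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
                         id_prefix: str = "SV",
                         id_width: int = 5) -> list[PopulationSv]:
    """Merge per-sample consensus SVs into the cohort call set.

    A sample contributing several calls to one cluster counts once toward
    the ``min_individuals`` threshold.  When a sample sheet is given, every
    sample carrying calls must appear in it, and breed/group sets are
    derived from the carriers.
    """
    if sample_sheet is not None:
        known = set(sample_sheet.sample_ids)
        unknown = set(per_sample) - known
        if unknown:
            raise ValueError(f"samples not in sample sheet: {sorted(unknown)}")

    pooled: list[ConsensusSv] = []
    for calls in per_sample.values():
        pooled.extend(calls)

    records = []
    for cluster in cluster_calls(pooled, min_overlap=min_overlap,
                                 ins_window=ins_window):
        carriers = frozenset(c.sample_id for c in cluster)
        if len(carriers) < min_individuals:
            continue
        sv_type = cluster[0].sv_type
        if sv_type == "INS":
            start = end = min(c.start for c in cluster)
            length = max(c.length for c in cluster)
        else:
            start = min(c.start for c in cluster)
            end = max(c.end for c in cluster)
            length = end - start
        truth_ids = frozenset().union(*(c.truth_ids for c in cluster))
        records.append((cluster[0].chrom, start, end, sv_type, length,
                        carriers, truth_ids))

    records.sort(key=lambda r: (chrom_sort_key(r[0]), r[1], r[2], r[3]))
    out = []
    for serial, (chrom, start, end, sv_type, length, carriers, truth_ids) \
            in enumerate(records, start=1):
        breeds = groups = frozenset()
        if sample_sheet is not None:
            breeds = frozenset(sample_sheet.breed_of(s) for s in carriers)
            groups = frozenset(sample_sheet.group_of(s) for s in carriers)
        out.append(PopulationSv(
            sv_id=f"{id_prefix}{serial:0{id_width}d}",
            chrom=chrom, start=start, end=end, sv_type=sv_type,
            length=length, carriers=carriers, breeds=breeds, groups=groups,
            truth_ids=truth_ids))
    return out


@dataclass
class PresenceMatrix:
    """Binary samples x SVs carrier matrix with breed/group row metadata."""

    matrix: pd.DataFrame       # index: sample_id, columns: sv_id, values 0/1
    sample_meta: pd.DataFrame  # index: sample_id, columns: breed, group

    def __post_init__(self):
        if not self.matrix.index.equals(self.sample_meta.index):
            raise ValueError("matrix rows and sample metadata disagree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def labels(self, level: str) -> pd.Series:
        if level not in ("group", "breed"):
            raise ValueError(f"unknown level {level!r}; expected 'group' or 'breed'")
        return self.sample_meta[level]

    def to_tsv(self, path) -> None:
        out = pd.concat([self.sample_meta, self.matrix], axis=1)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        meta = df[["breed", "group"]]
        mat = df.drop(columns=["breed", "group"]).astype(np.int8)
        return cls(mat, meta)


def build_presence_matrix(callset: Sequence[PopulationSv],
                          sample_sheet: SampleSheet) -> PresenceMatrix:
    """Cell (s, v) = 1 iff sample s carries population SV v.

    Every sample in the sheet gets a row, including samples that carry
    nothing; columns follow call-set ID order.
    """
    if not callset:
        raise ValueError("empty callset")
    samples = sample_sheet.sample_ids
    index = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), len(callset)), dtype=np.int8)
    for j, sv in enumerate(callset):
        for s in sv.carriers:
            mat[index[s], j] = 1
    matrix = pd.DataFrame(mat, index=pd.Index(samples, name="sample_id"),
                          columns=[sv.sv_id for sv in callset])
    meta = sample_sheet.table[["breed", "group"]].loc[samples]
    return PresenceMatrix(matrix, meta)
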