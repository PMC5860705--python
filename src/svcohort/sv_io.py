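"""Readers and writers for every external format the pipeline touches.

Structural-variant (SV) call tables come in two dialects: a neutral
tab-separated table (``chrom  start  end  type  support``, header required)
and VCF 4.2 with symbolic alleles and ``SVTYPE``/``END``/``SVLEN`` INFO
fields.  Gene models are read from GFF3 via :mod:`gffutils`; conserved-gene
lists, sample sheets and genotype count tables are plain CSV/text.

Coordinates are 0-based half-open internally, so ``length == end - start``
for deletions, duplications and inversions.  Insertions are stored as
zero-width breakpoints (``start == end``) with an explicit inserted length.
Chromosome names are normalised on ingest: a leading ``chr`` prefix is
stripped and the name case-folded, so ``chrX``, ``ChrX`` and ``x`` all
denote the same sequence.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

SV_TYPES = ("DEL", "INS", "DUP", "INV")
MIN_SV_LENGTH = 50


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and case-fold the chromosome name."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.casefold()


def chrom_sort_key(chrom: str):
    """Total order: numeric autosomes ascending, then X, then the rest."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    if c == "x":
        return (1, 0, "")
    return (2, 0, c)


@dataclass(frozen=True)
class SvCall:
    """One raw SV record emitted by a single caller for a single sample.

    ``truth_id`` is simulation bookkeeping: the identifier of the planted
    truth variant this call derives from, or ``None`` for real data and
    simulated false positives.
    """

    sample_id: str
    caller_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    support: int
    truth_id: str | None = None

    def validate(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems = []
        if self.sv_type not in SV_TYPES:
            problems.append("unsupported type")
        if self.start < 0 or self.end < 0:
            problems.append("negative coordinate")
        if self.end < self.start:
            problems.append("end before start")
        if self.sv_type == "INS":
            if self.start != self.end:
                problems.append("insertion breakpoint not zero-width")
        elif self.sv_type in SV_TYPES and self.length != self.end - self.start:
            problems.append("length inconsistent with span")
        if self.length < MIN_SV_LENGTH:
            problems.append("below minimum length")
        if self.support < 0:
            problems.append("negative support")
        return problems

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def sv_sort_key(call) -> tuple:
    return (*chrom_sort_key(call.chrom), call.start, call.end, call.sv_type)


@dataclass
class IngestResult:
    """Accepted calls plus a per-reason tally of rejected records."""

    calls: list[SvCall]
    rejections: Counter = field(default_factory=Counter)
    n_seen: int = 0

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)


def read_sv_calls(path, dialect: str, sample_id: str, caller_id: str) -> IngestResult:
    """Read one caller's SV table for one sample.

    ``dialect`` must be declared (``"tsv"`` or ``"vcf"``); caller-native
    formats are too ambiguous to sniff.  Records violating the SV
    invariants (unknown type, negative coordinates, length < 50 bp, ...)
    are dropped and counted per reason; everything returned is valid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        raw = _iter_tsv_records(path, sample_id, caller_id)
    elif dialect == "vcf":
        raw = _iter_vcf_records(path, sample_id, caller_id)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")

    result = IngestResult(calls=[])
    for call, parse_error in raw:
        result.n_seen += 1
        if parse_error is not None:
            result.rejections[parse_error] += 1
            continue
        problems = call.validate()
        if problems:
            result.rejections[problems[0]] += 1
        else:
            result.calls.append(call)
    return result


def _iter_tsv_records(path, sample_id, caller_id):
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return
        cols = {name.strip().casefold(): i for i, name in enumerate(header)}
        required = {"chrom", "start", "end", "type", "support"}
        if not required.issubset(cols):
            raise ValueError(f"{path}: TSV header must contain {sorted(required)}")
        has_truth = "truth_id" in cols
        for row in reader:
            if not row or all(not f.strip() for f in row):
                continue
            try:
                chrom = normalize_chrom(row[cols["chrom"]])
                start = int(row[cols["start"]])
                end = int(row[cols["end"]])
                sv_type = row[cols["type"]].strip().upper()
                support = int(row[cols["support"]])
            except (ValueError, IndexError):
                yield None, "malformed row"
                continue
            truth_id = None
            if has_truth and len(row) > cols["truth_id"]:
                truth_id = row[cols["truth_id"]].strip() or None
            length = end - start
            if sv_type == "INS":
                # zero-width breakpoint; the table encodes the inserted
                # length as end - start, which we fold into `length`
                length = end - start if end > start else 0
                yield SvCall(sample_id, caller_id, chrom, start, start,
                             "INS", length, support, truth_id), None
            else:
                yield SvCall(sample_id, caller_id, chrom, start, end,
                             sv_type, length, support, truth_id), None


def _iter_vcf_records(path, sample_id, caller_id):
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            sv_type = str(info.get("SVTYPE", "")).upper()
            chrom = normalize_chrom(rec.chrom)
            start = rec.start
            support = int(info.get("SUPPORT", 0))
            truth_id = info.get("TRUTH_ID", None)
            if truth_id is not None:
                truth_id = str(truth_id)
            if sv_type == "INS":
                svlen = info.get("SVLEN", None)
                if svlen is None:
                    yield None, "missing SVLEN for INS"
                    continue
                svlen = abs(int(svlen[0] if isinstance(svlen, tuple) else svlen))
                yield SvCall(sample_id, caller_id, chrom, start, start,
                             "INS", svlen, support, truth_id), None
            else:
                end = int(info.get("END", rec.stop))
                yield SvCall(sample_id, caller_id, chrom, start, end,
                             sv_type, end - start, support, truth_id), None


def write_sv_calls(calls: Iterable[SvCall], path) -> None:
    """Write calls as the neutral TSV dialect, in genomic order."""
    calls = sorted(calls, key=sv_sort_key)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "start", "end", "type", "support", "truth_id"])
        for c in calls:
            end = c.start + c.length if c.sv_type == "INS" else c.end
            writer.writerow([c.chrom, c.start, end, c.sv_type, c.support,
                             c.truth_id or ""])


# --------------------------------------------------------------------------
# sample sheets

@dataclass
class SampleSheet:
    """Cohort description: one breed and one group per sample, plus the
    per-caller input paths (columns named ``path_<caller_id>``)."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample_ids in sample sheet")
        for col in ("breed", "group"):
            if col not in self.table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def callers(self) -> list[str]:
        return [c[len("path_"):] for c in self.table.columns if c.startswith("path_")]

    def breed_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "breed"]

    def group_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "group"]

    def path_for(self, sample_id: str, caller_id: str) -> Path:
        return Path(self.table.at[sample_id, f"path_{caller_id}"])


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str).set_index("sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


# --------------------------------------------------------------------------
# gene models

@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utrs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[Transcript, ...]
    conserved: bool = False

    @property
    def transcript_count(self) -> int:
        return len(self.transcripts)


@dataclass
class GeneSet:
    genes: dict[str, Gene]

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def n_conserved(self) -> int:
        return sum(g.conserved for g in self)


def read_conserved_ids(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gene_models(path, conserved_ids: Iterable[str] = ()) -> GeneSet:
    """Load gene/mRNA/exon/CDS/UTR models from GFF3.

    Orphan features that cannot be resolved to a parent gene are skipped.
    An empty gene set is an error: every downstream annotation step would
    silently classify everything intergenic.
    """
    import gffutils

    conserved = set(conserved_ids)
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        raise ValueError(f"{path}: no usable gene models") from None
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = tuple(sorted((e.start - 1, e.end)
                                 for e in db.children(t, featuretype="exon")))
            cds = tuple(sorted((c.start - 1, c.end)
                               for c in db.children(t, featuretype="CDS")))
            utrs = tuple(sorted((u.start - 1, u.end)
                                for u in db.children(
                                    t, featuretype=("five_prime_UTR",
                                                    "three_prime_UTR", "UTR"))))
            transcripts.append(Transcript(t.id, exons, cds, utrs))
        if not transcripts:
            continue
        gid = g.id
        genes[gid] = Gene(
            gene_id=gid,
            symbol=g.attributes.get("Name", [gid])[0],
            biotype=g.attributes.get("biotype", ["protein_coding"])[0],
            chrom=normalize_chrom(g.seqid),
            strand=g.strand,
            start=g.start - 1,
            end=g.end,
            transcripts=tuple(transcripts),
            conserved=gid in conserved,
        )
    if not genes:
        raise ValueError(f"{path}: no usable gene models")
    return GeneSet(genes)


def write_gene_models(geneset: GeneSet, path) -> None:
    """Emit a GeneSet as GFF3 (1-based inclusive on output)."""
    lines = ["##gff-version 3"]
    for g in sorted(geneset, key=lambda g: (chrom_sort_key(g.chrom), g.start)):
        attrs = f"ID={g.gene_id};Name={g.symbol};biotype={g.biotype}"
        lines.append("\t".join([g.chrom, "svcohort", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]))
        for t in g.transcripts:
            lines.append("\t".join([g.chrom, "svcohort", "mRNA", str(g.start + 1),
                                    str(g.end), ".", g.strand, ".",
                                    f"ID={t.transcript_id};Parent={g.gene_id}"]))
            for kind, ivs in (("exon", t.exons), ("CDS", t.cds), ("UTR", t.utrs)):
                for i, (s, e) in enumerate(ivs):
                    fid = f"{t.transcript_id}.{kind}.{i}"
                    lines.append("\t".join(
                        [g.chrom, "svcohort", kind, str(s + 1), str(e), ".",
                         g.strand, "0" if kind == "CDS" else ".",
                         f"ID={fid};Parent={t.transcript_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# population call sets

def write_population_callset(callset, path, fmt: str = "tsv",
                             chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write the non-redundant cohort call set, sorted by (chrom, start).

    ``fmt="vcf"`` emits VCF 4.2 with symbolic ALTs and SVTYPE/END/SVLEN/
    SUPPORT-style INFO fields; carriers are stored in a CARRIERS INFO list.
    """
    ids = [sv.sv_id for sv in callset]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sv_ids in callset")
    ordered = sorted(callset, key=lambda s: (chrom_sort_key(s.chrom), s.start, s.sv_id))
    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sv_id", "chrom", "start", "end", "type",
                             "length", "carriers"])
            for sv in ordered:
                writer.writerow([sv.sv_id, sv.chrom, sv.start, sv.end, sv.sv_type,
                                 sv.length, ",".join(sorted(sv.carriers))])
    elif fmt == "vcf":
        _write_callset_vcf(ordered, path, chrom_lengths)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_callset_vcf(ordered, path, chrom_lengths):
    header = pysam.VariantHeader()
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "End position (1-based inclusive)")
    header.info.add("SVLEN", 1, "Integer",
                    "Inserted sequence length (insertions only; deletions, "
                    "duplications and inversions span POS..END)")
    header.info.add("CARRIERS", ".", "String", "Samples carrying the variant")
    if chrom_lengths is None:
        chrom_lengths = {}
        for sv in ordered:
            chrom_lengths[sv.chrom] = max(chrom_lengths.get(sv.chrom, 0),
                                          sv.end + 1)
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        header.contigs.add(chrom, length=int(chrom_lengths[chrom]))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for sv in ordered:
            rec = vf.new_record(
                contig=sv.chrom, start=sv.start,
                stop=max(sv.end, sv.start + 1),
                alleles=("N", f"<{sv.sv_type}>"), id=sv.sv_id)
            # pysam's new_record(stop=...) stores END one past the intended
            # 1-based inclusive end; reassigning stop writes it correctly.
            # SVLEN goes on insertions only: for span types htslib rederives
            # END as POS + SVLEN, which clashes with breakpoint coordinates.
            rec.stop = max(sv.end, sv.start + 1)
            rec.info["SVTYPE"] = sv.sv_type
            if sv.sv_type == "INS":
                rec.info["SVLEN"] = int(sv.length)
            if sv.carriers:
                rec.info["CARRIERS"] = sorted(sv.carriers)
            vf.write(rec)


def read_population_callset(path, fmt: str = "tsv"):
    """Read back a cohort call set written by :func:`write_population_callset`."""
    from .popmerge import PopulationSv

    out = []
    if fmt == "tsv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                carriers = frozenset(filter(None, row["carriers"].split(",")))
                out.append(PopulationSv(
                    sv_id=row["sv_id"], chrom=normalize_chrom(row["chrom"]),
                    start=int(row["start"]), end=int(row["end"]),
                    sv_type=row["type"], length=int(row["length"]),
                    carriers=carriers))
    elif fmt == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                sv_type = str(rec.info["SVTYPE"])
                start = rec.start
                end = start if sv_type == "INS" else rec.stop
                length = (abs(int(rec.info["SVLEN"]))
                          if sv_type == "INS" else end - start)
                carriers = frozenset(rec.info.get("CARRIERS", ()))
                out.append(PopulationSv(
                    sv_id=rec.id, chrom=normalize_chrom(rec.chrom),
                    start=start, end=end, sv_type=sv_type, length=length,
                    carriers=carriers))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return out


# --------------------------------------------------------------------------
# genotype count tables

@dataclass
class GenotypeTable:
    """Per-locus, per-population counts of the three biallelic
    insertion/deletion genotype classes II / ID / DD."""

    table: pd.DataFrame  # columns: locus_id, population_id, n_II, n_ID, n_DD

    COLUMNS = ("locus_id", "population_id", "n_II", "n_ID", "n_DD")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"genotype table missing columns {sorted(missing)}")
        counts = self.table[["n_II", "n_ID", "n_DD"]]
        if (counts < 0).any().any():
            raise ValueError("negative genotype counts")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("locus/population with all-zero counts")

    def counts(self, locus_id, population_id) -> dict[str, int]:
        row = self.table[(self.table.locus_id == locus_id)
                         & (self.table.population_id == population_id)].iloc[0]
        return {"II": int(row.n_II), "ID": int(row.n_ID), "DD": int(row.n_DD)}


def read_genotype_table(path) -> GenotypeTable:
    return GenotypeTable(pd.read_csv(path))


def write_genotype_table(gt: GenotypeTable, path) -> None:
    gt.table.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
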