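"""Synthetic cohorts with known truth for exercising the whole pipeline.

The generator emulates the structure of a multi-breed pig resequencing
cohort: a toy genome (three 10 Mb autosomes plus a 10 Mb X), a truth set
of structural variants with the observed type composition (~84% DEL,
8% INS, 7% DUP, 1% INV) and length-bin mix, three population groups each
split into breeds, carrier sets that are shared, group-specific or
breed-specific, two independent noisy callers per sample (detection
probability, uniform breakpoint jitter, Poisson false positives, shifted
Poisson read support), an optional SV density hotspot, toy gene models,
and Hardy-Weinberg genotype count tables.

Everything is deterministic under a fixed seed: each generator derives an
independent stream from ``SimConfig.seed`` via ``numpy`` seed sequences,
so regenerating one component never perturbs another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sv_io import (Gene, GeneSet, GenotypeTable, SampleSheet, SvCall,
                    Transcript, chrom_sort_key)

DEFAULT_CHROM_LENGTHS = {"1": 10_000_000, "2": 10_000_000,
                         "3": 10_000_000, "x": 10_000_000}
DEFAULT_TYPE_WEIGHTS = {"DEL": 0.84, "INS": 0.08, "DUP": 0.07, "INV": 0.01}
# length-bin weights follow the observed per-type bin composition of the
# cohort length table; insertions observed only between 50 and 132 bp
DEFAULT_BIN_WEIGHTS = {
    "DEL": (0.8955, 0.1005, 0.0040),
    "DUP": (0.7572, 0.2006, 0.0422),
    "INS": (1.0, 0.0, 0.0),
    "INV": (0.2993, 0.4489, 0.2518),
}
LENGTH_BINS = ((50, 1000), (1001, 10_000), (10_001, 100_000))
INS_LENGTH_RANGE = (50, 132)


@dataclass(frozen=True)
class CallerModel:
    caller_id: str
    detection_prob: float = 0.9
    jitter_bp: int = 10            # breakpoints jittered uniformly in [-j, j]
    fp_rate_per_mb: float = 1.0
    support_mean: float = 10.0     # support = 1 + Poisson(mean - 1)


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    start: int
    end: int
    factor: float  # placement weight multiplier inside the interval


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_truth_svs: int = 2000
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS))
    bin_weights: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_BIN_WEIGHTS))
    # cohort: (group, breed, n_samples) rows
    cohort: tuple[tuple[str, str, int], ...] = (
        ("GZP", "XP", 2), ("GZP", "KL", 2), ("GZP", "QB", 2),
        ("NPOG", "MIN", 2), ("NPOG", "JH", 2), ("NPOG", "TI", 2),
        ("EUP", "LW", 2), ("EUP", "DU", 2), ("EUP", "LA", 2),
    )
    baseline_carrier_prob: float = 0.3
    group_specific_fraction: float = 0.2
    breed_specific_fraction: float = 0.1
    callers: tuple[CallerModel, ...] = (CallerModel("pindel"),
                                        CallerModel("softsv"))
    hotspot: Hotspot | None = None
    # genotype table generation
    genotype_pops: tuple[str, ...] = ("XP", "KL", "QB", "GL", "LB", "LW", "DU", "RC")
    genotype_n_per_pop: int = 35
    genotype_n_loci: int = 6
    # toy gene models
    gene_mean_spacing: int = 60_000
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    transcripts_range: tuple[int, int] = (1, 10)
    conserved_fraction: float = 0.02

    def validate(self) -> None:
        if abs(sum(self.type_weights.values()) - 1.0) > 1e-9:
            raise ValueError("type weights must sum to 1")
        for m in self.callers:
            if not (0.0 <= m.detection_prob <= 1.0):
                raise ValueError("detection_prob must be in [0, 1]")
            if m.jitter_bp < 0:
                raise ValueError("jitter must be >= 0")
        for frac in (self.baseline_carrier_prob, self.group_specific_fraction,
                     self.breed_specific_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def sample_rows(self) -> list[tuple[str, str, str]]:
        """(sample_id, breed, group) for the whole cohort."""
        rows = []
        for group, breed, n in self.cohort:
            for k in range(1, n + 1):
                rows.append((f"{breed}{k}", breed, group))
        return rows

    def rng(self, label: str) -> np.random.Generator:
        """Independent deterministic stream per generator component."""
        digest = hashlib.sha256(label.encode()).digest()
        tag = int.from_bytes(digest[:4], "little")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(tag,)))


@dataclass(frozen=True)
class TruthSv:
    truth_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    carriers: frozenset[str]
    provenance: str  # shared | group:<G> | breed:<B>


@dataclass
class TruthSet:
    svs: list[TruthSv]
    config: SimConfig

    def __iter__(self):
        return iter(self.svs)

    def __len__(self):
        return len(self.svs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"truth_id": t.truth_id, "chrom": t.chrom, "start": t.start,
             "end": t.end, "type": t.sv_type, "length": t.length,
             "n_carriers": len(t.carriers),
             "carriers": ",".join(sorted(t.carriers)),
             "provenance": t.provenance}
            for t in self.svs])


def _sample_length(rng, sv_type, bin_weights) -> int:
    if sv_type == "INS":
        lo, hi = INS_LENGTH_RANGE
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))).clip(lo, hi))
    weights = np.asarray(bin_weights[sv_type], dtype=float)
    b = rng.choice(len(LENGTH_BINS), p=weights / weights.sum())
    lo, hi = LENGTH_BINS[b]
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))).clip(lo, hi))


def _place(rng, chrom_lengths, hotspot: Hotspot | None, length: int,
           max_tries: int = 1000) -> tuple[str, int]:
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lens.copy()
    if hotspot is not None and hotspot.factor > 1:
        i = chroms.index(hotspot.chrom)
        weights[i] += (hotspot.factor - 1) * (hotspot.end - hotspot.start)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        clen = chrom_lengths[chrom]
        if length >= clen:
            continue
        if hotspot is not None and chrom == hotspot.chrom and hotspot.factor > 1:
            span = hotspot.end - hotspot.start
            extra = (hotspot.factor - 1) * span
            if rng.uniform() < extra / (clen + extra):
                start = int(rng.integers(hotspot.start,
                                         max(hotspot.start + 1, hotspot.end - length)))
            else:
                start = int(rng.integers(0, clen - length))
        else:
            start = int(rng.integers(0, clen - length))
        return chrom, start
    raise RuntimeError("could not place SV: genome too small for its length")


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw the truth SV set and its carrier structure."""
    config.validate()
    rng = config.rng("truth")
    samples = config.sample_rows
    by_group: dict[str, list[str]] = {}
    by_breed: dict[str, list[str]] = {}
    for sid, breed, group in samples:
        by_group.setdefault(group, []).append(sid)
        by_breed.setdefault(breed, []).append(sid)
    groups = sorted(by_group)
    breeds = sorted(by_breed)

    types = sorted(config.type_weights)
    tw = np.array([config.type_weights[t] for t in types])
    svs = []
    width = max(5, len(str(config.n_truth_svs)))
    for i in range(config.n_truth_svs):
        sv_type = types[rng.choice(len(types), p=tw)]
        length = _sample_length(rng, sv_type, config.bin_weights)
        ref_len = 0 if sv_type == "INS" else length
        chrom, start = _place(rng, config.chrom_lengths, config.hotspot,
                              max(ref_len, 1))
        end = start if sv_type == "INS" else start + length

        u = rng.uniform()
        if u < config.group_specific_fraction:
            g = groups[rng.choice(len(groups))]
            pool, provenance = by_group[g], f"group:{g}"
        elif u < config.group_specific_fraction + config.breed_specific_fraction:
            b = breeds[rng.choice(len(breeds))]
            pool, provenance = by_breed[b], f"breed:{b}"
        else:
            pool, provenance = [s for s, _, _ in samples], "shared"
        carry = rng.uniform(size=len(pool)) < config.baseline_carrier_prob
        carriers = frozenset(s for s, c in zip(pool, carry) if c)
        svs.append(TruthSv(f"T{i + 1:0{width}d}", chrom, start, end,
                           sv_type, length, carriers, provenance))
    return TruthSet(svs, config)


def simulate_caller_calls(truth: TruthSet, config: SimConfig,
                          caller_id: str) -> dict[str, list[SvCall]]:
    """Per-sample raw call lists for one caller.

    Each carrier x truth SV is detected with the caller's probability;
    detected breakpoints are jittered independently and uniformly within
    +-jitter_bp (insertion breakpoints jitter as a point, inserted length
    unchanged).  False positives arrive as a Poisson process per sample at
    the configured rate per Mb, with random type and length and no truth
    tag.  Deterministic given the config seed and caller_id.
    """
    model = next((m for m in config.callers if m.caller_id == caller_id), None)
    if model is None:
        raise ValueError(f"no caller model named {caller_id!r}")
    rng = config.rng(f"caller:{caller_id}")
    samples = config.sample_rows
    out: dict[str, list[SvCall]] = {sid: [] for sid, _, _ in samples}

    def support() -> int:
        return 1 + int(rng.poisson(max(model.support_mean - 1, 0)))

    for t in truth:
        clen = config.chrom_lengths[t.chrom]
        for sid in sorted(t.carriers):
            if rng.uniform() >= model.detection_prob:
                continue
            j = model.jitter_bp
            if t.sv_type == "INS":
                pos = t.start + int(rng.integers(-j, j + 1)) if j else t.start
                pos = int(np.clip(pos, 0, clen - 1))
                out[sid].append(SvCall(sid, caller_id, t.chrom, pos, pos,
                                       "INS", t.length, support(), t.truth_id))
            else:
                s = t.start + (int(rng.integers(-j, j + 1)) if j else 0)
                e = t.end + (int(rng.integers(-j, j + 1)) if j else 0)
                s = int(np.clip(s, 0, clen - 1))
                e = int(np.clip(e, s + 50, clen))  # keep a valid >=50 bp span
                out[sid].append(SvCall(sid, caller_id, t.chrom, s, e,
                                       t.sv_type, e - s, support(), t.truth_id))

    genome_mb = sum(config.chrom_lengths.values()) / 1e6
    types = sorted(config.type_weights)
    tw = np.array([config.type_weights[t] for t in types])
    for sid, _, _ in samples:
        n_fp = rng.poisson(model.fp_rate_per_mb * genome_mb)
        for _ in range(n_fp):
            sv_type = types[rng.choice(len(types), p=tw)]
            length = _sample_length(rng, sv_type, config.bin_weights)
            ref_len = 0 if sv_type == "INS" else length
            chrom, start = _place(rng, config.chrom_lengths, None,
                                  max(ref_len, 1))
            end = start if sv_type == "INS" else start + length
            out[sid].append(SvCall(sid, caller_id, chrom, start, end,
                                   sv_type, length, support(), None))
    for sid in out:
        out[sid].sort(key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end))
    return out


def sample_sheet(config: SimConfig, call_dir=None) -> SampleSheet:
    """Cohort sample sheet; per-caller path columns point into call_dir
    when given (file naming matches :func:`write_cohort`)."""
    rows = []
    for sid, breed, group in config.sample_rows:
        row = {"sample_id": sid, "breed": breed, "group": group}
        for m in config.callers:
            path = (f"{call_dir}/{sid}.{m.caller_id}.tsv"
                    if call_dir is not None else "")
            row[f"path_{m.caller_id}"] = path
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(df)


def simulate_genotype_table(config: SimConfig,
                            freqs: Mapping[str, Mapping[str, float]] | None = None
                            ) -> GenotypeTable:
    """Hardy-Weinberg genotype class counts per locus and population.

    ``freqs`` maps locus_id -> population_id -> deletion-allele frequency
    p_D; when omitted, frequencies are drawn uniformly on (0.05, 0.95).
    """
    rng = config.rng("genotypes")
    if freqs is None:
        freqs = {f"L{i + 1}": {pop: float(rng.uniform(0.05, 0.95))
                               for pop in config.genotype_pops}
                 for i in range(config.genotype_n_loci)}
    rows = []
    for locus in freqs:
        for pop, p_d in freqs[locus].items():
            probs = [(1 - p_d) ** 2, 2 * p_d * (1 - p_d), p_d ** 2]
            n_ii, n_id, n_dd = rng.multinomial(config.genotype_n_per_pop, probs)
            rows.append({"locus_id": locus, "population_id": pop,
                         "n_II": int(n_ii), "n_ID": int(n_id), "n_DD": int(n_dd)})
    return GenotypeTable(pd.DataFrame(rows))


def simulate_gene_models(config: SimConfig) -> GeneSet:
    """Non-overlapping toy genes with 1-10 transcripts of exon/CDS/UTR
    structure and a small conserved subset."""
    rng = config.rng("genes")
    genes: dict[str, Gene] = {}
    gid_n = 0
    for chrom in sorted(config.chrom_lengths, key=chrom_sort_key):
        clen = config.chrom_lengths[chrom]
        pos = int(rng.integers(1000, config.gene_mean_spacing))
        while True:
            glen = int(rng.integers(*config.gene_length_range))
            if pos + glen >= clen - 1000:
                break
            gid_n += 1
            gid = f"GENE{gid_n:05d}"
            strand = "+" if rng.uniform() < 0.5 else "-"
            n_exons = int(rng.integers(3, 9))
            # partition the gene span into alternating exon/intron blocks
            cuts = np.sort(rng.choice(
                np.arange(pos + 200, pos + glen - 200, 100),
                size=2 * n_exons - 2, replace=False))
            bounds = [pos, *map(int, cuts), pos + glen]
            exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
            n_tr = int(rng.integers(config.transcripts_range[0],
                                    config.transcripts_range[1] + 1))
            transcripts = []
            for k in range(n_tr):
                # each transcript keeps a contiguous exon run
                a = int(rng.integers(0, n_exons)) if n_tr > 1 else 0
                b = int(rng.integers(a, n_exons)) if n_tr > 1 else n_exons - 1
                t_exons = tuple(exons[a:b + 1])
                utr5 = (t_exons[0][0], min(t_exons[0][0] + 50, t_exons[0][1]))
                utr3 = (max(t_exons[-1][1] - 50, t_exons[-1][0]), t_exons[-1][1])
                cds = []
                for s, e in t_exons:
                    cs, ce = max(s, utr5[1]), min(e, utr3[0])
                    if ce > cs:
                        cds.append((cs, ce))
                transcripts.append(Transcript(
                    f"{gid}.t{k + 1}", t_exons, tuple(cds),
                    tuple(sorted({utr5, utr3}))))
            genes[gid] = Gene(gid, gid, "protein_coding", chrom, strand,
                              pos, pos + glen, tuple(transcripts),
                              conserved=bool(rng.uniform() < config.conserved_fraction))
            pos += glen + int(rng.integers(1000, config.gene_mean_spacing))
    return GeneSet(genes)


# --------------------------------------------------------------------------
# analytic truth bookkeeping

def detection_prob_after_filter(model: CallerModel, min_support: int = 3) -> float:
    """Probability a carrier's true call survives the support filter:
    detection_prob x P(1 + Poisson(mean-1) >= min_support)."""
    from scipy import stats as sstats
    lam = max(model.support_mean - 1, 0)
    p_support = float(sstats.poisson.sf(min_support - 2, lam)) \
        if min_support > 1 else 1.0
    return model.detection_prob * p_support


def expected_recall(truth: TruthSet, config: SimConfig,
                    min_support: int = 3, min_individuals: int = 2,
                    excluded_chroms: Sequence[str] = ("y",)) -> tuple[float, float]:
    """Analytic expectation and SD of the recovered-truth-SV count.

    A truth SV survives when >= min_individuals of its carriers have it
    detected by every caller (each at its effective post-filter detection
    probability).  Returns (expected count, binomial-style SD).
    """
    from scipy import stats as sstats
    p_both = 1.0
    for m in config.callers:
        p_both *= detection_prob_after_filter(m, min_support)
    mean = 0.0
    var = 0.0
    excluded = set(excluded_chroms)
    for t in truth:
        if t.chrom in excluded:
            continue
        c = len(t.carriers)
        p_keep = float(1 - sstats.binom.cdf(min_individuals - 1, c, p_both)) \
            if c >= min_individuals else 0.0
        mean += p_keep
        var += p_keep * (1 - p_keep)
    return mean, float(np.sqrt(var))
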