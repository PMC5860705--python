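"""Published summary tables from the multi-breed pig SV resequencing
cohort, used as worked-example inputs.

These are the printed per-sample sequencing QC table, the cohort SV type
counts, the per-type length-bin table, the conserved-gene overlap
marginals and one published deletion record.  They are inputs to the
package's arithmetic (the raw reads and caller outputs behind them are
not redistributable), letting the summary and test-statistic operations
be exercised against the published values.
"""

from __future__ import annotations

import pandas as pd

# Per-sample sequencing and mapping statistics for the 18 resequenced
# Guizhou pigs (Gb of raw/clean/mapped bases, mapping rate, mean depth,
# Q20 and GC percentages).
SEQUENCING_SUMMARY = pd.DataFrame(
    [
        ("KL1", 29.51, 28.64, 27.31, 95.36, 11.17, 97.66, 42.77),
        ("KL2", 31.20, 30.32, 29.21, 96.34, 11.95, 97.75, 42.62),
        ("KL3", 34.76, 33.59, 32.51, 96.78, 13.30, 97.40, 42.44),
        ("QB1", 29.94, 28.85, 27.91, 96.74, 11.42, 97.39, 42.06),
        ("QB2", 30.72, 29.69, 28.75, 96.83, 11.76, 97.38, 42.30),
        ("QB3", 28.90, 27.81, 26.72, 96.08, 10.93, 97.33, 42.19),
        ("GL1", 29.20, 28.01, 27.15, 96.93, 11.10, 96.56, 42.82),
        ("GL2", 29.42, 28.49, 27.59, 96.84, 11.28, 96.95, 42.95),
        ("GL3", 28.38, 27.33, 26.51, 97.00, 10.84, 96.73, 42.99),
        ("LB1", 28.86, 27.39, 26.47, 96.64, 10.83, 96.76, 42.96),
        ("LB2", 28.10, 26.97, 26.15, 96.96, 10.70, 96.83, 43.05),
        ("LB3", 28.23, 26.77, 26.02, 97.20, 10.64, 96.61, 42.72),
        ("XP1", 30.11, 28.31, 27.42, 96.86, 11.21, 96.30, 42.52),
        ("XP2", 33.52, 31.69, 30.63, 96.66, 12.53, 96.50, 42.26),
        ("XP3", 48.46, 42.25, 39.82, 94.25, 16.29, 92.90, 42.42),
        ("XP4", 29.22, 27.41, 26.56, 96.90, 10.87, 96.50, 42.64),
        ("XP5", 30.88, 29.20, 28.22, 96.64, 11.54, 96.19, 42.94),
        ("XP6", 48.62, 42.68, 40.23, 94.26, 16.45, 92.75, 41.73),
    ],
    columns=["sample_id", "raw_gb", "clean_gb", "mapped_gb", "map_ratio_pct",
             "depth_x", "q20_pct", "gc_pct"],
).set_index("sample_id")

# Cohort non-redundant call-set type counts (39,166 SVs total).
TYPE_COUNTS = {"DEL": 32750, "INS": 3268, "DUP": 2747, "INV": 401}

# Per-type length-bin table: (count, total length in bp) per closed bin.
LENGTH_BIN_TABLE = pd.DataFrame(
    {
        "DEL_N": [29326, 3293, 131], "DEL_L": [8397430, 10531040, 1722145],
        "DUP_N": [2080, 551, 116], "DUP_L": [454370, 1912944, 2367314],
        "INS_N": [3268, 0, 0], "INS_L": [243903, 0, 0],
        "INV_N": [120, 180, 101], "INV_L": [58038, 754322, 1338534],
    },
    index=pd.Index(["50-1000 bp", "1-10 kb", "10-100 kb"], name="bin"),
)

# Conserved-gene depletion marginals: of 437 conserved (core eukaryotic)
# genes mapped into the pig annotation, 112 contained an SV; of 25,880
# annotated genes in total, 7,881 contained or neighboured an SV.
CONSERVED_GENES_TOTAL = 437
CONSERVED_GENES_WITH_SV = 112
GENES_TOTAL = 25880
GENES_WITH_SV = 7881

# One published deletion record (ID GZsv12513): chromosome 6,
# start 20,311,318, end 20,311,590, printed length 272 bp — the worked
# example for the half-open coordinate convention.
EXAMPLE_RECORD = {"sv_id": "GZsv12513", "chrom": "6", "start": 20_311_318,
                  "end": 20_311_590, "length": 272, "sv_type": "DEL"}
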