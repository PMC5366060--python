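"""Collapse aligned sequences into unique haplotypes and summarise the alignment.

Haplotype identity is exact string equality after case-folding: ambiguity
codes and gaps are compared literally, so an 'N' produces a distinct
haplotype.  This is deliberately conservative — any similarity-based merging
rule would be an invention — and a warning is emitted when 'N' or '-' occur.

Difference counting and divergence are uncorrected (raw p-distance): a
difference is tallied only at sites where both sequences carry an unambiguous
base (A/C/G/T) and those bases differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from matrilog.seq_io import Alignment, write_table

_UNAMBIGUOUS = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypeTable:
    """Unique haplotypes of an alignment plus per-sample assignment.

    Indices are dense from 0, ordered by first occurrence in the alignment.
    """

    haplotypes: list[str]
    assignment: dict[str, int]
    length: int
    gc_percent: float
    s_sites: int

    @property
    def n_hap(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        """Number of samples carrying each haplotype."""
        tally = [0] * self.n_hap
        for idx in self.assignment.values():
            tally[idx] += 1
        return tally

    def samples_of(self, index: int) -> list[str]:
        return [sid for sid, idx in self.assignment.items() if idx == index]


def _seq_matrix(alignment: Alignment) -> np.ndarray:
    """Alignment as an (n, length) byte matrix, uppercased."""
    joined = "".join(s.upper() for s in alignment.records.values())
    return np.frombuffer(joined.encode("ascii"), dtype="S1").reshape(alignment.n, alignment.length)


def _gc_and_s(matrix: np.ndarray) -> tuple[float, int]:
    unamb = np.isin(matrix, _UNAMBIGUOUS)
    n_unamb = int(unamb.sum())
    if n_unamb == 0:
        gc = 0.0
    else:
        gc = 100.0 * int(np.isin(matrix, np.frombuffer(b"GC", dtype="S1")).sum()) / n_unamb
    # segregating site: >=2 distinct unambiguous bases in the column
    distinct = np.zeros(matrix.shape[1], dtype=int)
    for base in _UNAMBIGUOUS:
        distinct += (matrix == base).any(axis=0)
    s_sites = int((distinct >= 2).sum())
    return gc, s_sites


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Group samples by exact (case-folded) sequence identity.

    Two samples share a haplotype index iff their sequences are identical
    after uppercasing; haplotype indices follow first occurrence.
    """
    seen: dict[str, int] = {}
    haplotypes: list[str] = []
    assignment: dict[str, int] = {}
    any_ambiguous = False
    for sid, seq in alignment.records.items():
        key = seq.upper()
        if "N" in key or "-" in key:
            any_ambiguous = True
        if key not in seen:
            seen[key] = len(haplotypes)
            haplotypes.append(key)
        assignment[sid] = seen[key]
    if any_ambiguous:
        warnings.warn(
            "alignment contains 'N' or gap characters; haplotype identity is literal, "
            "so ambiguous sequences form distinct haplotypes",
            stacklevel=2,
        )
    matrix = _seq_matrix(alignment)
    gc, s_sites = _gc_and_s(matrix)
    return HaplotypeTable(
        haplotypes=haplotypes,
        assignment=assignment,
        length=alignment.length,
        gc_percent=round(gc, 1),
        s_sites=s_sites,
    )


def pairwise_differences(hap_a: str, hap_b: str) -> int:
    """Number of sites where both sequences carry differing unambiguous bases.

    Symmetric; 0 for identical unambiguous sequences.  Sites where either
    sequence has an ambiguity code, 'N' or a gap are excluded (pairwise
    complete), matching an uncorrected nucleotide-difference count.
    """
    if len(hap_a) != len(hap_b):
        raise ValueError(f"unequal lengths: {len(hap_a)} vs {len(hap_b)}")
    a = np.frombuffer(hap_a.upper().encode("ascii"), dtype="S1")
    b = np.frombuffer(hap_b.upper().encode("ascii"), dtype="S1")
    valid = np.isin(a, _UNAMBIGUOUS) & np.isin(b, _UNAMBIGUOUS)
    return int(((a != b) & valid).sum())


def percent_divergence(n_diff: int, length: int) -> float:
    """Uncorrected sequence divergence as a percentage, rounded to 1 decimal."""
    if length <= 0:
        raise ValueError("alignment length must be positive")
    if not 0 <= n_diff <= length:
        raise ValueError(f"n_diff {n_diff} outside [0, {length}]")
    return round(100.0 * n_diff / length, 1)


def alignment_summary(alignment: Alignment) -> dict[str, float | int]:
    """Summary statistics: length, G+C% (unambiguous bases only), S, N_hap."""
    table = collapse_haplotypes(alignment)
    return {
        "length": table.length,
        "gc_percent": table.gc_percent,
        "s_sites": table.s_sites,
        "n_hap": table.n_hap,
    }


def haplotype_frame(table: HaplotypeTable) -> pd.DataFrame:
    counts = table.counts
    return pd.DataFrame(
        {
            "haplotype_index": range(table.n_hap),
            "count": counts,
            "sample_ids": [",".join(table.samples_of(i)) for i in range(table.n_hap)],
            "representative_sequence": table.haplotypes,
        }
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path, header_lines=()) -> None:
    """Write the haplotype table as TSV (index, count, sample ids, sequence)."""
    write_table(haplotype_frame(table), path, header_lines)
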