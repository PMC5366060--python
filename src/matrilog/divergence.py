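"""Within-log pairwise nucleotide-difference distribution and its partitioning.

For every multi-haplotype log, all unordered pairs of distinct haplotypes
present in the log contribute one record (redundant haplotypes are omitted, so
only non-zero differences are tallied).  Pairs from MF logs are partitioned by
whether they are provably between-family: under strict maternal inheritance,
two haplotypes each carried by at least one female in the log must belong to
two distinct matrilines.  Pairs involving a male-only haplotype are ambiguous
(the male could be the father of the other carriers' family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from matrilog.classify import LogAssemblage, LogClass, classify_log
from matrilog.haplotypes import HaplotypeTable, pairwise_differences
from matrilog.seq_io import write_table

BETWEEN_FAMILY = "between_family"
AMBIGUOUS = "ambiguous"
OMH_PAIR = "omh"


@dataclass(frozen=True)
class DiffRecord:
    """One non-redundant within-log haplotype pair and its difference count."""

    log_id: str
    hap_i: int
    hap_j: int
    n_diff: int
    log_class: str
    attribution: str


def attribute_pair(hap_i: int, hap_j: int, assemblage: LogAssemblage, log_class: LogClass) -> str:
    """Attribution label for a within-log haplotype pair.

    OMH-log pairs are labelled ``omh``.  In an MF log a pair is
    ``between_family`` iff each haplotype is carried by at least one female in
    the log (two distinct maternal matrilines are then certain); otherwise it
    is ``ambiguous``.
    """
    if log_class is not LogClass.MF:
        return OMH_PAIR
    if assemblage.females_with(hap_i) >= 1 and assemblage.females_with(hap_j) >= 1:
        return BETWEEN_FAMILY
    return AMBIGUOUS


def within_log_pairs(
    assemblages: Sequence[LogAssemblage], table: HaplotypeTable
) -> list[DiffRecord]:
    """All non-redundant within-log haplotype pairs with their difference counts.

    A log with h distinct haplotypes contributes C(h, 2) records; SH logs
    contribute nothing.  Pairs of distinct haplotypes that differ only at
    ambiguous sites (difference count 0) are dropped with a warning, keeping
    the tally strictly non-zero.
    """
    records: list[DiffRecord] = []
    for a in assemblages:
        log_class = classify_log(a)
        if log_class is LogClass.SH:
            continue
        haps = sorted({m.haplotype for m in a.members})
        for hi, hj in combinations(haps, 2):
            n_diff = pairwise_differences(table.haplotypes[hi], table.haplotypes[hj])
            if n_diff == 0:
                warnings.warn(
                    f"log {a.log_id!r}: haplotypes {hi} and {hj} differ only at "
                    "ambiguous sites; pair omitted",
                    stacklevel=2,
                )
                continue
            records.append(
                DiffRecord(
                    log_id=a.log_id,
                    hap_i=hi,
                    hap_j=hj,
                    n_diff=n_diff,
                    log_class=log_class.value,
                    attribution=attribute_pair(hi, hj, a, log_class),
                )
            )
    return records


def records_frame(records: Sequence[DiffRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "log_id": r.log_id,
                "hap_i": r.hap_i,
                "hap_j": r.hap_j,
                "n_diff": r.n_diff,
                "log_class": r.log_class,
                "attribution": r.attribution,
            }
            for r in records
        ],
        columns=["log_id", "hap_i", "hap_j", "n_diff", "log_class", "attribution"],
    )


@dataclass
class DiffHistogram:
    """Integer-binned within-log difference distribution, stacked by attribution.

    ``table`` has one row per bin 1..max with columns total, between_family,
    ambiguous and omh.  ``fraction_le2`` is the share of pairs at most two
    differences apart; ``ambiguous_fraction_mf`` is the share of MF-log pairs
    that could not be attributed to a between-family comparison.
    """

    table: pd.DataFrame
    n_records: int
    fraction_le2: float
    ambiguous_fraction_mf: float | None


def build_histogram(records: Sequence[DiffRecord]) -> DiffHistogram:
    """Tally records into unit-width integer bins 1..max(n_diff)."""
    if not records:
        raise ValueError("no difference records to histogram")
    max_bin = max(r.n_diff for r in records)
    bins = range(1, max_bin + 1)
    tallies = {b: {"total": 0, BETWEEN_FAMILY: 0, AMBIGUOUS: 0, OMH_PAIR: 0} for b in bins}
    for r in records:
        tallies[r.n_diff]["total"] += 1
        tallies[r.n_diff][r.attribution] += 1
    table = pd.DataFrame(
        [
            {
                "bin": b,
                "total": t["total"],
                "between_family": t[BETWEEN_FAMILY],
                "ambiguous": t[AMBIGUOUS],
                "omh": t[OMH_PAIR],
            }
            for b, t in tallies.items()
        ]
    )
    n_mf = sum(r.log_class == "MF" for r in records)
    n_amb = sum(r.attribution == AMBIGUOUS for r in records)
    return DiffHistogram(
        table=table,
        n_records=len(records),
        fraction_le2=sum(r.n_diff <= 2 for r in records) / len(records),
        ambiguous_fraction_mf=(n_amb / n_mf) if n_mf else None,
    )


@dataclass
class PairedTResult:
    """Paired t-test over the binned difference distributions of two log classes."""

    t: float
    df: int
    p: float
    alternative: str
    n_bins: int


def compare_distributions(
    records: Sequence[DiffRecord],
    max_bin: int | None = None,
    alternative: str = "two-sided",
) -> PairedTResult:
    """Paired t-test of the MF vs OMH binned difference distributions.

    Per-bin pair counts for bins 1..max_bin are paired across the two log
    classes and the t-test runs on the bin-wise differences (df = max_bin - 1).
    ``alternative`` is 'two-sided' (default), 'greater' or 'less'.
    """
    mf = [r.n_diff for r in records if r.log_class == "MF"]
    omh = [r.n_diff for r in records if r.log_class == "OMH"]
    if not mf or not omh:
        raise ValueError("both MF and OMH records are required")
    if max_bin is None:
        max_bin = max(max(mf), max(omh))
    if max_bin < 2:
        raise ValueError("max_bin must be >= 2")
    mf_counts = np.bincount(mf, minlength=max_bin + 1)[1 : max_bin + 1]
    omh_counts = np.bincount(omh, minlength=max_bin + 1)[1 : max_bin + 1]
    if np.array_equal(mf_counts, omh_counts):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(mf_counts, omh_counts, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedTResult(t=t, df=max_bin - 1, p=p, alternative=alternative, n_bins=max_bin)


def write_records(records: Sequence[DiffRecord], path: str | Path, header_lines=()) -> None:
    write_table(records_frame(records), path, header_lines)


def write_histogram(hist: DiffHistogram, path: str | Path, header_lines=()) -> None:
    write_table(hist.table, path, header_lines)


def plot_histogram(hist: DiffHistogram, path: str | Path) -> None:
    """Stacked-bar plot of the difference distribution.

    Between-family MF pairs in black, ambiguous MF pairs in grey, OMH pairs in
    white, stacked per integer bin.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = hist.table
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(t["bin"], t["between_family"], color="black", edgecolor="black", label="between-family (MF)")
    ax.bar(t["bin"], t["ambiguous"], bottom=t["between_family"], color="0.7",
           edgecolor="black", label="ambiguous (MF)")
    ax.bar(t["bin"], t["omh"], bottom=t["between_family"] + t["ambiguous"], color="white",
           edgecolor="black", label="OMH")
    ax.set_xlabel("Nucleotide differences between co-occurring haplotypes")
    ax.set_ylabel("Frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
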