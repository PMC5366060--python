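"""Classify logs as SH / OMH / MF by single-family consistency, plus sex-ratio tests.

The inference rests on three premises: mtDNA is strictly maternally inherited
and non-recombining; de-novo mutation within a family is negligible over the
sequenced region; and a family is founded by one monogamous male-female pair.
Under these premises every member of a single family except the father carries
the mother's haplotype (the father carries his own mother's haplotype, from
outside the family).  An assemblage of sampled adults is therefore consistent
with a single family iff all members share one haplotype except at most one
member, who must be male.

Labels:

* ``SH``  — single haplotype: exactly one distinct haplotype in the log.
* ``OMH`` — other multi-haplotype: multiple haplotypes but consistent with a
  single founding pair (e.g. father + mother/offspring).
* ``MF``  — multi-family: inconsistent with a single founding pair — three or
  more haplotypes, or two haplotypes where the minority haplotype has two or
  more carriers, or where its sole carrier is female.

Individuals of unknown sex are treated as male for classification: males can
never trigger the two-different-females rule, so MF calls remain a lower bound.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from matrilog.haplotypes import HaplotypeTable
from matrilog.seq_io import FEMALE, IndividualRecord


class LogClass(str, Enum):
    SH = "SH"
    OMH = "OMH"
    MF = "MF"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Member:
    """One sampled adult within a log: id, haplotype index and sex."""

    sample_id: str
    haplotype: int
    sex: str  # 'M', 'F' or 'U'


@dataclass
class LogAssemblage:
    """The sampled adults of one log, with location."""

    log_id: str
    members: list[Member]
    latitude: float | None = None
    longitude: float | None = None
    elevation: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"log {self.log_id!r}: empty assemblage")

    @property
    def n_haplotypes(self) -> int:
        return len({m.haplotype for m in self.members})

    @property
    def n_females(self) -> int:
        return sum(m.sex == FEMALE for m in self.members)

    @property
    def n_males(self) -> int:
        return sum(m.sex != FEMALE for m in self.members)

    def females_with(self, haplotype: int) -> int:
        return sum(m.sex == FEMALE and m.haplotype == haplotype for m in self.members)


def build_assemblages(
    records: Sequence[IndividualRecord], table: HaplotypeTable
) -> list[LogAssemblage]:
    """Group individuals by log, attaching haplotype indices and coordinates.

    Assemblages are ordered by log id and members by sample id, so the result
    is invariant to input row order.  Log coordinates/elevation are the means
    over members (identical per log in well-formed data).
    """
    by_log: dict[str, list[IndividualRecord]] = {}
    for rec in records:
        by_log.setdefault(rec.log_id, []).append(rec)
    assemblages = []
    for log_id in sorted(by_log):
        recs = sorted(by_log[log_id], key=lambda r: r.sample_id)
        members = [Member(r.sample_id, table.assignment[r.sample_id], r.sex) for r in recs]
        elevs = [r.elevation for r in recs if r.elevation is not None]
        assemblages.append(
            LogAssemblage(
                log_id=log_id,
                members=members,
                latitude=float(np.mean([r.latitude for r in recs])),
                longitude=float(np.mean([r.longitude for r in recs])),
                elevation=float(np.mean(elevs)) if elevs else None,
            )
        )
    return assemblages


def classify_log(assemblage: LogAssemblage | Iterable[Member]) -> LogClass:
    """Label one assemblage SH, OMH or MF by single-family consistency.

    Equivalent to an exhaustive search over role assignments (at most one
    father; mother, sons and daughters share the maternal haplotype): the
    assemblage is consistent with one founding pair iff some haplotype is
    carried by exactly one member, that member is male (or of unknown sex),
    and all remaining members share the other haplotype.
    """
    members = assemblage.members if isinstance(assemblage, LogAssemblage) else list(assemblage)
    if not members:
        raise ValueError("empty assemblage")
    counts = Counter(m.haplotype for m in members)
    if len(counts) == 1:
        return LogClass.SH
    if len(counts) >= 3:
        return LogClass.MF
    # exactly two haplotypes: consistent iff a singleton haplotype exists whose
    # carrier is not female (that carrier can be the father)
    for hap, n in counts.items():
        if n == 1:
            carrier = next(m for m in members if m.haplotype == hap)
            if carrier.sex != FEMALE:
                return LogClass.OMH
    return LogClass.MF


def classify_all(assemblages: Sequence[LogAssemblage]) -> pd.DataFrame:
    """Classify every assemblage; one row per log.

    Columns: log_id, log_class, n_members, n_haplotypes, n_females, n_males,
    latitude, longitude, elevation.
    """
    rows = []
    for a in assemblages:
        rows.append(
            {
                "log_id": a.log_id,
                "log_class": classify_log(a).value,
                "n_members": len(a.members),
                "n_haplotypes": a.n_haplotypes,
                "n_females": a.n_females,
                "n_males": a.n_males,
                "latitude": a.latitude,
                "longitude": a.longitude,
                "elevation": a.elevation,
            }
        )
    return pd.DataFrame(rows)


def summarize_classes(class_table: pd.DataFrame) -> dict[str, int]:
    """Per-class log counts and whole-percent shares (plus the multi-haplotype total)."""
    n = len(class_table)
    counts = class_table["log_class"].value_counts().to_dict()
    out: dict[str, int] = {"n_logs": n}
    for cls in ("SH", "OMH", "MF"):
        c = int(counts.get(cls, 0))
        out[f"n_{cls.lower()}"] = c
        out[f"pct_{cls.lower()}"] = round(100.0 * c / n) if n else 0
    multi = int(counts.get("OMH", 0)) + int(counts.get("MF", 0))
    out["n_multi_haplotype"] = multi
    out["pct_multi_haplotype"] = round(100.0 * multi / n) if n else 0
    return out


@dataclass
class SexRatioResult:
    """Pearson goodness-of-fit chi-square test of a 1:1 sex ratio (df = 1)."""

    n_female: int
    n_male: int
    chi2: float
    df: int
    p: float

    @property
    def n(self) -> int:
        return self.n_female + self.n_male

    @property
    def pct_female(self) -> int:
        return round(100.0 * self.n_female / self.n)


def sex_ratio_test(n_female: int, n_male: int) -> SexRatioResult:
    """Chi-square goodness of fit against a 1:1 sex ratio, no continuity correction."""
    n = n_female + n_male
    if n < 1:
        raise ValueError("no observations")
    chi2, p = stats.chisquare([n_female, n_male])
    return SexRatioResult(n_female=n_female, n_male=n_male, chi2=float(chi2), df=1, p=float(p))


def sex_ratio_for_classes(
    assemblages: Sequence[LogAssemblage],
    class_table: pd.DataFrame,
    log_classes: Sequence[str],
) -> SexRatioResult:
    """Sex-ratio test over all individuals of the logs in the given class(es).

    Individuals of unknown sex are excluded (the test needs a determined sex).
    """
    wanted = set(class_table.loc[class_table["log_class"].isin(log_classes), "log_id"])
    nf = nm = 0
    for a in assemblages:
        if a.log_id in wanted:
            for m in a.members:
                if m.sex == FEMALE:
                    nf += 1
                elif m.sex == "M":
                    nm += 1
    return sex_ratio_test(nf, nm)
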