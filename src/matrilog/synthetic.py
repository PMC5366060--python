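"""Forward simulation of sub-social log colonisation with full ground truth.

The generator emulates the study's sampling design: logs scattered over a
southern-Appalachian-sized landscape, each colonised by one (or, with
probability ``p_multi_family``, two) monogamous founding pairs; strict
maternal mtDNA inheritance with zero de-novo mutation within families by
default; and two or three sexed adults sampled per log.

Maternal haplotypes are drawn from a serial-chain haplotype pool: lineage i+1
derives from lineage i by a geometric number of substitutions at fresh sites,
so chain distance equals nucleotide distance exactly.  Co-occurring families
(and the father's own matriline) draw from nearby chain positions, producing
the right-skewed within-log divergence distribution characteristic of
close-relative colonisation, with the geometric tail supplying occasional
larger divergences.  A locality flag disables this, making matriline draws
uniform over the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from matrilog.seq_io import Alignment, IndividualRecord, write_alignment, write_metadata

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FATHER, MOTHER, OFFSPRING = "father", "mother", "offspring"


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters of the simulator.

    Defaults mirror the sampling design being emulated: 88 logs, 2-3 sampled
    adults per log with mean 2.78, a 1,125-bp marker with G+C near one third,
    and a right-skewed divergence distribution among co-occurring matrilines.
    ``p_multi_family`` defaults to 0.40 — above the 22% observed frequency of
    multi-family logs, which is a lower bound on the true co-occurrence rate
    because a 2-3 adult sample detects a second family only when it includes
    females of two distinct matrilines (or three haplotypes).  Under these
    defaults the classified SH/OMH/MF fractions land near the observed ones.
    """

    n_logs: int = 88
    lat_range: tuple[float, float] = (33.5, 38.5)
    lon_range: tuple[float, float] = (-85.5, -79.5)
    elevation_range: tuple[float, float] = (300.0, 1700.0)
    p_multi_family: float = 0.40
    p_three_adults: float = 0.78  # gives E[adults per log] = 2.78
    seq_length: int = 1125
    gc_content: float = 0.338
    n_lineages: int = 60
    mean_step_mutations: float = 1.2  # geometric mean substitutions per chain step
    locality: bool = True
    max_family_offset: int = 2  # chain steps between co-occurring matrilines
    max_father_offset: int = 3  # chain steps between mates' matrilines
    p_father_same_matriline: float = 0.5  # local mating: mates share a matriline haplotype
    p_father_present: float = 0.8
    n_offspring: int = 2  # not-yet-dispersed adult offspring per family
    offspring_female_prob: float = 0.5
    de_novo_mutation_rate: float = 0.0  # expected de-novo substitutions per offspring
    spatial_clustering_strength: float = 0.0  # 0 = uniform MF placement
    ensure_detectable: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_multi_family", "p_three_adults", "p_father_present",
                     "p_father_same_matriline", "offspring_female_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_logs < 2:
            raise ValueError("n_logs must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for every simulated individual and log.

    ``individuals`` columns: sample_id, log_id, family, role, sex, chain_pos
    (haplotype position in the pool chain; -1 if de-novo mutated).
    ``logs`` columns: log_id, n_families_present, n_families_sampled,
    true_multi_family, latitude, longitude, elevation.
    """

    individuals: pd.DataFrame
    logs: pd.DataFrame
    pool: list[str]
    params: SimParams


def generate_haplotype_pool(
    n_lineages: int,
    seq_length: int,
    mean_step_mutations: float = 1.5,
    gc_content: float = 0.338,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """A serial chain of haplotypes with additive, exactly-known divergences.

    Lineage 0 is a random ancestral sequence; lineage i+1 copies lineage i and
    substitutes a geometric (mean ``mean_step_mutations``, support >= 1) number
    of sites.  Mutated sites are drawn without replacement across the whole
    chain, so the difference count between chain positions i < j equals the sum
    of the step sizes between them.
    """
    rng = np.random.default_rng() if rng is None else rng
    if mean_step_mutations < 1.0:
        raise ValueError("mean_step_mutations must be >= 1 (at least one substitution per step)")
    p_base = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    ancestral = rng.choice(_BASES, size=seq_length, p=p_base)
    if n_lineages == 1:
        return [ancestral.tobytes().decode("ascii")]
    steps = rng.geometric(1.0 / mean_step_mutations, size=n_lineages - 1)
    total = int(steps.sum())
    if total > seq_length:
        raise ValueError(
            f"requested {total} mutations exceed sequence length {seq_length}; "
            "reduce n_lineages or mean_step_mutations"
        )
    positions = rng.choice(seq_length, size=total, replace=False)
    pool = [ancestral.copy()]
    used = 0
    for m in steps:
        seq = pool[-1].copy()
        for pos in positions[used : used + m]:
            current = seq[pos]
            others = _BASES[_BASES != current]
            seq[pos] = rng.choice(others)
        used += m
        pool.append(seq)
    return [s.tobytes().decode("ascii") for s in pool]


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    for pos in rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False):
        others = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(others)
    return arr.tobytes().decode("ascii")


def _place_logs(params: SimParams, multi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Log coordinates; MF logs optionally drawn around a common cluster centre."""
    lat0, lat1 = params.lat_range
    lon0, lon1 = params.lon_range
    coords = np.column_stack(
        [rng.uniform(lat0, lat1, params.n_logs), rng.uniform(lon0, lon1, params.n_logs)]
    )
    s = params.spatial_clustering_strength
    if s > 0 and multi.any():
        center = np.array([rng.uniform(lat0, lat1), rng.uniform(lon0, lon1)])
        sigma = np.array([lat1 - lat0, lon1 - lon0]) * 0.5 / (1.0 + 4.0 * s)
        n_mf = int(multi.sum())
        clustered = center + rng.normal(0.0, 1.0, size=(n_mf, 2)) * sigma
        clustered[:, 0] = np.clip(clustered[:, 0], lat0, lat1)
        clustered[:, 1] = np.clip(clustered[:, 1], lon0, lon1)
        coords[multi] = clustered
    return coords


def populate_and_sample(
    params: SimParams,
) -> tuple[Alignment, list[IndividualRecord], SyntheticTruth]:
    """Simulate colonisation and sampling; return alignment, metadata and truth.

    Each log hosts one family (probability 1 - ``p_multi_family``) or two.  A
    family is a father (carrying his own maternal haplotype, present in the
    adult roster with probability ``p_father_present``), a mother, and
    ``n_offspring`` adult offspring carrying the mother's haplotype.  Two or
    three adults are sampled per log without replacement from the pooled
    roster of its resident families.  With ``ensure_detectable`` every
    multi-family log's sample is forced to include the two mothers (two
    females with distinct haplotypes), making co-occurrence detectable by
    construction.
    """
    rng = np.random.default_rng(params.seed)
    pool = generate_haplotype_pool(
        params.n_lineages,
        params.seq_length,
        params.mean_step_mutations,
        params.gc_content,
        rng,
    )
    L = len(pool)
    multi = rng.random(params.n_logs) < params.p_multi_family
    coords = _place_logs(params, multi, rng)
    elevations = rng.uniform(*params.elevation_range, size=params.n_logs)

    seqs: dict[str, str] = {}
    meta: list[IndividualRecord] = []
    ind_rows: list[dict] = []
    log_rows: list[dict] = []

    for li in range(params.n_logs):
        log_id = f"L{li + 1:03d}"
        n_fam = 2 if multi[li] else 1
        # maternal chain positions for the log's families
        max_span = params.max_family_offset * (n_fam - 1)
        if params.locality:
            base = int(rng.integers(0, max(1, L - max_span)))
            fam_pos = [base]
            for _ in range(n_fam - 1):
                fam_pos.append(min(L - 1, fam_pos[-1] + int(rng.integers(1, params.max_family_offset + 1))))
        else:
            fam_pos = list(rng.choice(L, size=min(n_fam, L), replace=False))
            while len(fam_pos) < n_fam:  # tiny pools: allow repeats as a last resort
                fam_pos.append(int(rng.integers(0, L)))

        roster: list[tuple[int, str, str, int]] = []  # (family, role, sex, chain_pos)
        for fi, mpos in enumerate(fam_pos):
            if rng.random() < params.p_father_same_matriline:
                fpos = mpos
            elif params.locality:
                off = int(rng.choice([-1, 1]) * rng.integers(1, params.max_father_offset + 1))
                fpos = int(np.clip(mpos + off, 0, L - 1))
            else:
                fpos = int(rng.integers(0, L))
            if rng.random() < params.p_father_present:
                roster.append((fi, FATHER, "M", fpos))
            roster.append((fi, MOTHER, "F", mpos))
            for _ in range(params.n_offspring):
                sex = "F" if rng.random() < params.offspring_female_prob else "M"
                roster.append((fi, OFFSPRING, sex, mpos))

        n_adults = 3 if rng.random() < params.p_three_adults else 2
        n_adults = min(n_adults, len(roster))
        if params.ensure_detectable and n_fam >= 2:
            mothers = [i for i, r in enumerate(roster) if r[1] == MOTHER]
            chosen = list(mothers[:2])
            others = [i for i in range(len(roster)) if i not in chosen]
            extra = max(0, n_adults - len(chosen))
            chosen += list(rng.choice(others, size=extra, replace=False))
        else:
            chosen = list(rng.choice(len(roster), size=n_adults, replace=False))

        sampled_fams = set()
        for si, ri in enumerate(sorted(chosen)):
            fam, role, sex, cpos = roster[ri]
            sampled_fams.add(fam)
            sid = f"{log_id}-{si + 1}"
            seq = pool[cpos]
            if role == OFFSPRING and params.de_novo_mutation_rate > 0:
                n_mut = int(rng.poisson(params.de_novo_mutation_rate))
                if n_mut:
                    seq = _mutate(seq, n_mut, rng)
                    cpos = -1
            seqs[sid] = seq
            meta.append(
                IndividualRecord(
                    sample_id=sid,
                    log_id=log_id,
                    sex=sex,
                    latitude=round(float(coords[li, 0]), 6),
                    longitude=round(float(coords[li, 1]), 6),
                    elevation=round(float(elevations[li]), 1),
                )
            )
            ind_rows.append(
                {
                    "sample_id": sid,
                    "log_id": log_id,
                    "family": fam,
                    "role": role,
                    "sex": sex,
                    "chain_pos": cpos,
                }
            )
        log_rows.append(
            {
                "log_id": log_id,
                "n_families_present": n_fam,
                "n_families_sampled": len(sampled_fams),
                "true_multi_family": bool(n_fam >= 2),
                "latitude": round(float(coords[li, 0]), 6),
                "longitude": round(float(coords[li, 1]), 6),
                "elevation": round(float(elevations[li]), 1),
            }
        )

    truth = SyntheticTruth(
        individuals=pd.DataFrame(ind_rows),
        logs=pd.DataFrame(log_rows),
        pool=pool,
        params=params,
    )
    return Alignment(seqs), meta, truth


def write_bundle(
    out_dir: str | Path,
    alignment: Alignment,
    records: list[IndividualRecord],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the simulated bundle: FASTA, metadata TSV and two truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "alignment.fasta",
        "metadata": out / "metadata.tsv",
        "truth_individuals": out / "truth_individuals.tsv",
        "truth_logs": out / "truth_logs.tsv",
    }
    write_alignment(alignment, paths["fasta"])
    write_metadata(records, paths["metadata"])
    truth.individuals.to_csv(paths["truth_individuals"], sep="\t", index=False)
    truth.logs.to_csv(paths["truth_logs"], sep="\t", index=False)
    return paths


def with_params(params: SimParams, **overrides) -> SimParams:
    """A copy of ``params`` with the given fields replaced."""
    return replace(params, **overrides)
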