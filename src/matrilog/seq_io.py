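"""Read and validate the two study inputs, and write tabular outputs.

Inputs are (a) a FASTA file holding an alignment of concatenated mtDNA
sequences, one record per sampled adult, and (b) a delimited metadata table
with one row per adult: sample id, log id, sex, latitude, longitude and
(optionally) elevation.  Both readers validate aggressively: the downstream
classification is sex- and haplotype-dependent, so silent coercion of a bad
sex code or a truncated sequence would corrupt the biology, not just the
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes, plus 'N' and the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Accepted sex synonyms (matched case-insensitively after stripping).
SEX_SYNONYMS = {
    "m": "M", "male": "M", "♂": "M",
    "f": "F", "female": "F", "♀": "F",
}

MALE, FEMALE, UNKNOWN_SEX = "M", "F", "U"

METADATA_COLUMNS = ("sample_id", "log_id", "sex", "latitude", "longitude", "elevation")


class InputError(ValueError):
    """Raised when an input file fails validation."""


@dataclass
class Alignment:
    """An equal-length nucleotide alignment keyed by sample id.

    ``records`` preserves input order.  Sequences may contain IUPAC ambiguity
    codes, 'N' and the gap character '-'; validation is case-insensitive but
    the stored strings keep their original case.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment is empty")
        lengths = {sid: len(seq) for sid, seq in self.records.items()}
        distinct = set(lengths.values())
        if len(distinct) != 1:
            offenders = ", ".join(f"{sid}={n}" for sid, n in list(lengths.items())[:10])
            raise InputError(f"unequal lengths in alignment: {offenders}")
        if 0 in distinct:
            raise InputError("alignment contains empty sequences")
        for sid, seq in self.records.items():
            bad = set(seq.upper()) - IUPAC_CHARS
            if bad:
                pos = next(i for i, c in enumerate(seq.upper()) if c in bad)
                raise InputError(
                    f"illegal character {seq[pos]!r} at position {pos} in record {sid!r}"
                )

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return len(next(iter(self.records.values())))

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class IndividualRecord:
    """One sampled adult: identity, log membership, sex and location."""

    sample_id: str
    log_id: str
    sex: str  # 'M', 'F' or 'U' (unknown)
    latitude: float
    longitude: float
    elevation: float | None = None

    def __post_init__(self) -> None:
        if not self.log_id:
            raise InputError(f"record {self.sample_id!r}: empty log_id")
        if self.sex not in (MALE, FEMALE, UNKNOWN_SEX):
            raise InputError(f"record {self.sample_id!r}: invalid sex {self.sex!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise InputError(f"record {self.sample_id!r}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise InputError(f"record {self.sample_id!r}: longitude {self.longitude} out of range")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment, validating lengths, ids and characters.

    Record order is preserved as read.  Duplicate ids, unequal lengths and
    non-IUPAC characters are hard errors naming the offending record.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate sample id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment back to FASTA (round-trips with :func:`read_alignment`)."""
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment.records.items()]
    SeqIO.write(recs, str(path), "fasta")


def _detect_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _parse_sex(raw: object, row: int, unknown_token: str | None) -> str:
    token = str(raw).strip()
    key = token.casefold()
    if key in SEX_SYNONYMS:
        return SEX_SYNONYMS[key]
    if unknown_token is not None and key == unknown_token.casefold():
        return UNKNOWN_SEX
    raise InputError(f"metadata row {row}: unrecognised sex code {token!r}")


def _parse_float(raw: object, row: int, col: str, optional: bool = False) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        if optional:
            return None
        raise InputError(f"metadata row {row}: missing {col}")
    text = str(raw).strip()
    if text == "" or text.lower() in ("na", "nan"):
        if optional:
            return None
        raise InputError(f"metadata row {row}: missing {col}")
    try:
        return float(text)
    except ValueError as exc:
        raise InputError(f"metadata row {row}: non-numeric {col} {text!r}") from exc


def read_metadata(
    path: str | Path,
    alignment: Alignment | None = None,
    delimiter: str | None = None,
    unknown_sex_token: str | None = None,
) -> list[IndividualRecord]:
    """Read the per-individual metadata table.

    The delimiter is auto-detected between tab and comma unless given.  Sex
    codes accept {M, male, ♂} / {F, female, ♀} case-insensitively; any other
    token is an error unless it equals ``unknown_sex_token``, in which case the
    sex is recorded as unknown ('U').  When ``alignment`` is supplied every
    sample_id must have a sequence.  Logs with a single sampled individual are
    retained but flagged with a warning (they can only ever classify as SH).
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in ("sample_id", "log_id", "sex", "latitude", "longitude") if c not in df.columns]
    if missing:
        raise InputError(f"metadata missing required columns: {', '.join(missing)}")
    has_elev = "elevation" in df.columns

    records: list[IndividualRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.sample_id).strip()
        if sid in seen:
            raise InputError(f"metadata row {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        log_id = str(row.log_id).strip()
        records.append(
            IndividualRecord(
                sample_id=sid,
                log_id=log_id,
                sex=_parse_sex(row.sex, i, unknown_sex_token),
                latitude=_parse_float(row.latitude, i, "latitude"),
                longitude=_parse_float(row.longitude, i, "longitude"),
                elevation=_parse_float(row.elevation, i, "elevation", optional=True) if has_elev else None,
            )
        )

    if alignment is not None:
        absent = [r.sample_id for r in records if r.sample_id not in alignment.records]
        if absent:
            raise InputError(
                f"metadata sample ids absent from alignment: {', '.join(absent[:10])}"
            )
        extra = set(alignment.records) - seen
        if extra:
            warnings.warn(
                f"{len(extra)} alignment record(s) have no metadata row and are ignored",
                stacklevel=2,
            )

    log_sizes: dict[str, int] = {}
    for r in records:
        log_sizes[r.log_id] = log_sizes.get(r.log_id, 0) + 1
    singletons = sorted(lid for lid, n in log_sizes.items() if n == 1)
    if singletons:
        warnings.warn(
            f"log(s) with a single sampled individual (classifiable only as SH): "
            f"{', '.join(singletons[:10])}",
            stacklevel=2,
        )
    return records


def write_metadata(records: Iterable[IndividualRecord], path: str | Path, delimiter: str = "\t") -> None:
    """Write individual records as a delimited table with the fixed column order."""
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "log_id": r.log_id,
                "sex": r.sex,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "elevation": r.elevation,
            }
            for r in records
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def write_table(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a DataFrame as UTF-8 TSV, with optional '#'-prefixed header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
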