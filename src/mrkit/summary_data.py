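"""Domain types and text I/O for GWAS summary statistics.

The in-memory model mirrors what a two-sample MR analysis needs from a
summary-level GWAS: one record per SNP carrying the effect/other allele,
effect-allele frequency (optional — some consortia do not release it), the
per-allele effect estimate with its standard error, the association p-value
and the sample size.  Effects on binary traits are log odds ratios; effects
on continuous traits are in trait-SD or native units.

File formats are plain tab-separated text:

* summary TSV — header ``SNP CHR POS EA OA EAF BETA SE P N``, ``NA`` for
  missing values; a column mapping adapts foreign dialects.
* LD matrix TSV — first column and header are SNP ids, body is pairwise r2.
* annotation TSV — ``SNP TRAIT P``, linking SNPs to traits for confounder
  screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import importlib.resources
import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "VALID_BASES",
    "SummaryRecord",
    "Study",
    "LDMatrix",
    "TraitAnnotation",
    "read_summary_tsv",
    "write_summary_tsv",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_annotations",
    "load_table1_fixture",
]

VALID_BASES = frozenset("ACGT")

#: canonical column order of the summary TSV dialect
SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate (log odds for binary traits),
    ``se`` its standard error.  ``eaf`` may be ``None``: some consortia
    (e.g. GLIDE) do not publish effect-allele frequencies.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: n must be positive, got {self.n}")


@dataclass
class Study:
    """An ordered collection of :class:`SummaryRecord` for one trait."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    records: dict[str, SummaryRecord] = field(default_factory=dict)
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValidationError(f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}")

    @property
    def is_binary(self) -> bool:
        return self.trait_type == "binary"

    def add(self, record: SummaryRecord) -> None:
        if record.snp_id in self.records:
            raise ValidationError(f"duplicate snp_id {record.snp_id} in study {self.trait_name!r}")
        self.records[record.snp_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> SummaryRecord:
        return self.records[snp_id]


@dataclass(frozen=True)
class TraitAnnotation:
    """A reported SNP-trait association used for confounder screening."""

    snp_id: str
    trait: str
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}/{self.trait}: p-value must be in (0, 1]")


class LDMatrix:
    """Pairwise squared-correlation (r2) matrix over a set of SNPs."""

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray, *, tol: float = 1e-9):
        r2 = np.asarray(r2, dtype=float)
        snp_ids = list(snp_ids)
        if r2.ndim != 2 or r2.shape[0] != r2.shape[1] or r2.shape[0] != len(snp_ids):
            raise ValidationError("LD matrix must be square with one row per SNP id")
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("LD matrix SNP ids must be unique")
        if np.any(r2 < -tol) or np.any(r2 > 1 + tol):
            raise ValidationError("LD r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(r2), 1.0, atol=tol):
            raise ValidationError("LD matrix diagonal must be 1")
        if not np.allclose(r2, r2.T, atol=tol):
            raise ValidationError("LD matrix must be symmetric")
        self.snp_ids = snp_ids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        """r2 between two SNPs; ``default`` when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])


# ---------------------------------------------------------------------------
# text I/O


def _fmt(value, *, is_int: bool = False) -> str:
    if value is None:
        return "NA"
    if is_int:
        return str(int(value))
    # repr round-trips floats exactly through the text representation
    return repr(float(value))


def _parse_optional_float(token) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip()
    if s == "" or s.upper() == "NA":
        return None
    return float(s)


def _parse_optional_int(token) -> int | None:
    v = _parse_optional_float(token)
    return None if v is None else int(v)


def read_summary_tsv(
    path: str | Path,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
) -> Study:
    """Read a GWAS summary-statistics TSV into a :class:`Study`.

    ``column_map`` maps canonical names (``SNP``, ``EA``, ...) to the file's
    own header names for foreign dialects.  ``NA``/empty tokens in optional
    columns (CHR, POS, EAF, N) parse as absent.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = dict(column_map or {})
    mandatory = ["SNP", "EA", "OA", "BETA", "SE", "P"]
    resolved = {}
    for canon in SUMMARY_COLUMNS:
        name = colmap.get(canon, canon)
        if name in df.columns:
            resolved[canon] = name
        elif canon in mandatory:
            raise ConfigurationError(f"{path}: missing mandatory column {name!r} (for {canon})")
    study = Study(trait_name=trait_name or path.stem, trait_type=trait_type)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        get = lambda c: row.get(resolved[c]) if c in resolved else None
        try:
            record = SummaryRecord(
                snp_id=str(get("SNP")).strip(),
                effect_allele=str(get("EA")).strip().upper(),
                other_allele=str(get("OA")).strip().upper(),
                beta=float(get("BETA")),
                se=float(get("SE")),
                pvalue=float(get("P")),
                eaf=_parse_optional_float(get("EAF")),
                chrom=(str(get("CHR")).strip() or None) if get("CHR") not in (None, "", "NA") else None,
                pos=_parse_optional_int(get("POS")),
                n=_parse_optional_int(get("N")),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
        study.add(record)
    return study


def write_summary_tsv(study: Study, path: str | Path) -> None:
    """Write a :class:`Study` in the canonical summary dialect.

    Floats are written with ``repr`` so that read(write(s)) reproduces every
    field bit-for-bit.
    """
    path = Path(path)
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for r in study:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom if r.chrom is not None else "NA",
                    _fmt(r.pos, is_int=True),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pvalue),
                    _fmt(r.n, is_int=True),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an r2 matrix TSV whose header row and first column are SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column SNP labels differ")
    return LDMatrix(list(df.index), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(Path(path), sep="\t")


def read_annotations(path: str | Path) -> list[TraitAnnotation]:
    """Read a ``SNP TRAIT P`` annotation table."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "TRAIT": str})
    for col in ("SNP", "TRAIT", "P"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    return [
        TraitAnnotation(snp_id=row.SNP, trait=row.TRAIT, pvalue=float(row.P))
        for row in df.itertuples(index=False)
    ]


def load_table1_fixture() -> tuple[Study, Study]:
    """The packaged worked example: 8 instruments for continuous coffee
    consumption (exposure, N = 375,833) paired with their periodontitis
    associations from GLIDE (binary outcome, N = 49,066; EAF unpublished).

    Returns ``(exposure, outcome)`` with values exactly as published.
    """
    data = importlib.resources.files("mrkit.data")
    with importlib.resources.as_file(data / "coffee_continuous_exposure.tsv") as p:
        exposure = read_summary_tsv(p, "continuous", trait_name="coffee consumption (cups/day)")
    with importlib.resources.as_file(data / "periodontitis_outcome.tsv") as p:
        outcome = read_summary_tsv(p, "binary", trait_name="periodontitis")
    exposure.n_total = 375833
    outcome.n_total = 49066
    outcome.n_cases = 17672
    outcome.n_controls = 31394
    return exposure, outcome
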