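"""Reading, validation and writing of GWAS summary statistics.

All file dialects are handled here. The canonical on-disk format is a
tab-separated table with header columns

    SNP  CHR  POS  EA  OA  EAF  BETA  SE  P  N  [N_CASES  N_CONTROLS]

one row per variant. ``BETA`` is the additive effect per copy of the
effect allele ``EA``: SD units for continuous traits, log odds ratio for
binary traits. Positions are 1-based. Alleles are uppercased on read;
only single-base SNP alleles are accepted (the analyses this package
supports use SNP instruments only, so indels are rejected).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical field name -> canonical column header
CANONICAL_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
}

OPTIONAL_FIELDS = frozenset({"n_cases", "n_controls"})


class SumstatsError(ValueError):
    """Base class for summary-statistics file and validation errors."""


class ColumnError(SumstatsError):
    """A required column is missing from the file or column map."""


class DuplicateSNPError(SumstatsError):
    """The same variant identifier occurs more than once in one panel."""

    def __init__(self, duplicates: list[str]):
        self.duplicates = duplicates
        super().__init__(f"duplicate snp_id values: {', '.join(duplicates)}")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    n_cases: int | None = None
    n_controls: int | None = None

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        out = []
        if self.effect_allele not in VALID_BASES:
            out.append(f"effect allele {self.effect_allele!r} is not a single base")
        if self.other_allele not in VALID_BASES:
            out.append(f"other allele {self.other_allele!r} is not a single base")
        if self.effect_allele == self.other_allele:
            out.append("effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            out.append(f"eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            out.append(f"se {self.se} is not positive")
        if not 0.0 < self.pvalue <= 1.0:
            out.append(f"p-value {self.pvalue} outside (0, 1]")
        if self.pos < 1:
            out.append(f"position {self.pos} is not 1-based")
        if self.n < 0:
            out.append(f"sample size {self.n} is negative")
        if self.n_cases is not None and self.n_cases < 0:
            out.append("n_cases is negative")
        if self.n_controls is not None and self.n_controls < 0:
            out.append("n_controls is negative")
        if (
            self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n
        ):
            out.append(
                f"n_cases + n_controls = {self.n_cases + self.n_controls} != n = {self.n}"
            )
        return out

    def validate(self) -> "VariantAssociation":
        probs = self.problems()
        if probs:
            raise SumstatsError(f"{self.snp_id}: " + "; ".join(probs))
        return self

    def flipped(self) -> "VariantAssociation":
        """The same association reported for the opposite allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class StudyPanel:
    """A GWAS source dataset: one trait, a set of per-variant associations.

    ``records`` preserves input order and is keyed by ``snp_id`` (unique
    within a panel). Binary traits carry case/control counts either on
    the panel or on every record.
    """

    trait_name: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    sd_units: str | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        return self.records[snp_id]

    def add(self, rec: VariantAssociation) -> None:
        if rec.snp_id in self.records:
            raise DuplicateSNPError([rec.snp_id])
        self.records[rec.snp_id] = rec

    def validate(self) -> "StudyPanel":
        for rec in self:
            rec.validate()
        if self.trait_type == "binary":
            panel_counts = self.n_cases is not None and self.n_controls is not None
            per_record = all(
                r.n_cases is not None and r.n_controls is not None for r in self
            )
            if not (panel_counts or per_record):
                raise SumstatsError(
                    f"binary trait {self.trait_name!r} needs case/control counts "
                    "on the panel or on every record"
                )
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            rows.append(
                {
                    "SNP": r.snp_id,
                    "CHR": r.chrom,
                    "POS": r.pos,
                    "EA": r.effect_allele,
                    "OA": r.other_allele,
                    "EAF": r.eaf,
                    "BETA": r.beta,
                    "SE": r.se,
                    "P": r.pvalue,
                    "N": r.n,
                    "N_CASES": r.n_cases,
                    "N_CONTROLS": r.n_controls,
                }
            )
        return pd.DataFrame(
            rows, columns=list(CANONICAL_COLUMNS.values())
        )


@dataclass(frozen=True)
class RowRejection:
    line_number: int  # 1-based line in the file, header included
    snp_id: str | None
    reason: str


def _parse_int(value: str, what: str) -> int:
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"unparsable {what}: {value!r}") from None
    if not f.is_integer():
        raise ValueError(f"{what} {value!r} is not an integer")
    return int(f)


def _parse_float(value: str, what: str) -> float:
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"unparsable {what}: {value!r}") from None
    if math.isnan(f):
        raise ValueError(f"{what} is NaN")
    return f


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
    trait_name: str | None = None,
    trait_type: str = "continuous",
    sd_units: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> tuple[StudyPanel, list[RowRejection]]:
    """Read a summary-statistics table into a validated :class:`StudyPanel`.

    ``column_map`` maps canonical field names (``snp_id``, ``beta``, ...)
    to the column headers used in the file; by default the canonical
    headers (``SNP``, ``BETA``, ...) are assumed. The separator is taken
    from ``sep`` — never guessed.

    Rows violating record invariants are rejected, not fatal: they are
    logged to standard error with their 1-based line numbers and returned
    alongside the panel. Missing required columns and duplicated variant
    identifiers are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for fieldname, col in colmap.items():
        if fieldname in OPTIONAL_FIELDS:
            continue
        if col not in df.columns:
            raise ColumnError(
                f"{path.name}: required column {col!r} (for {fieldname!r}) not found"
            )

    panel = StudyPanel(
        trait_name=trait_name if trait_name is not None else path.stem,
        trait_type=trait_type,
        sd_units=sd_units,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    rejections: list[RowRejection] = []
    seen_dupes: list[str] = []

    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # line 1 is the header
        rowd = dict(zip(df.columns, row))
        snp_id = str(rowd.get(colmap["snp_id"], "")).strip()
        try:
            rec = VariantAssociation(
                snp_id=snp_id,
                chrom=str(rowd[colmap["chrom"]]).strip(),
                pos=_parse_int(rowd[colmap["pos"]], "position"),
                effect_allele=str(rowd[colmap["effect_allele"]]).strip().upper(),
                other_allele=str(rowd[colmap["other_allele"]]).strip().upper(),
                eaf=_parse_float(rowd[colmap["eaf"]], "eaf"),
                beta=_parse_float(rowd[colmap["beta"]], "beta"),
                se=_parse_float(rowd[colmap["se"]], "se"),
                pvalue=_parse_float(rowd[colmap["pvalue"]], "p-value"),
                n=_parse_int(rowd[colmap["n"]], "sample size"),
                n_cases=_opt_int(rowd, colmap["n_cases"]),
                n_controls=_opt_int(rowd, colmap["n_controls"]),
            )
        except (ValueError, KeyError) as exc:
            rejections.append(RowRejection(line_no, snp_id or None, str(exc)))
            logger.error("%s line %d: %s", path.name, line_no, exc)
            continue
        probs = rec.problems()
        if probs:
            rejections.append(RowRejection(line_no, rec.snp_id, "; ".join(probs)))
            logger.error("%s line %d (%s): %s", path.name, line_no, rec.snp_id, "; ".join(probs))
            continue
        if rec.snp_id in panel.records:
            seen_dupes.append(rec.snp_id)
            continue
        panel.records[rec.snp_id] = rec

    if seen_dupes:
        raise DuplicateSNPError(sorted(set(seen_dupes)))
    return panel, rejections


def _opt_int(rowd: Mapping[str, str], col: str) -> int | None:
    val = rowd.get(col, "")
    val = str(val).strip()
    if val in ("", "NA", "nan", "None"):
        return None
    return _parse_int(val, col)


def write_summary_stats(panel: StudyPanel, path: str | Path) -> Path:
    """Write a panel in the canonical tab-separated format.

    Floats are written with :func:`repr`, which round-trips bit-exactly
    through :func:`read_summary_stats`.
    """
    path = Path(path)
    cols = list(CANONICAL_COLUMNS.values())
    lines = ["\t".join(cols)]
    for r in panel:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    repr(float(r.eaf)),
                    repr(float(r.beta)),
                    repr(float(r.se)),
                    repr(float(r.pvalue)),
                    str(r.n),
                    "" if r.n_cases is None else str(r.n_cases),
                    "" if r.n_controls is None else str(r.n_controls),
                ]
            )
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise SumstatsError(f"cannot write {path}: {exc}") from exc
    return path


def panels_equal(a: StudyPanel, b: StudyPanel) -> bool:
    """Record-by-record equality of two panels (order-sensitive)."""
    if len(a) != len(b):
        return False
    return all(ra == rb for ra, rb in zip(a, b))
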