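"""Reading, validating and writing study-level summary tables.

Two record schemas are supported, mirroring how genetic association
meta-analyses tabulate their source studies:

* case-control records (binary outcome): sample sizes, risk-allele
  frequencies, optional genotype counts, optional reported OR with 95% CI;
* quantitative-trait records: sample size, per-genotype trait summaries
  (n, mean, SD) and/or a per-allele regression coefficient with SE/CI/p.

Files are UTF-8 delimited text (comma by default, tab selectable) with a
required header.  Missing cells are the literal ``NA`` (blank cells are
treated the same); decimal points only, no thousands separators.  Genotype
triples are ordered (hom-risk, het, hom-other), with the risk allele named
per record.

Two curated tables of published *G6PC2* study characteristics ship with the
package: :func:`load_t2d_studies` (18 case-control studies of type 2
diabetes at rs560887/rs16856187) and :func:`load_fg_studies` (35
quantitative-trait studies of fasting glucose at
rs560887/rs573225/rs16856187).
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "CaseControlStudy",
    "QuantStudy",
    "SnpRaf",
    "StudyTable",
    "read_case_control_table",
    "read_quant_table",
    "write_case_control_table",
    "write_quant_table",
    "write_results_table",
    "read_results_table",
    "load_t2d_studies",
    "load_fg_studies",
]

ETHNICITIES = ("Caucasian", "Asian", "African-American", "mixed")

_ETHNICITY_ALIASES = {
    "caucasian": "Caucasian",
    "caucasians": "Caucasian",
    "asian": "Asian",
    "asians": "Asian",
    "african-american": "African-American",
    "african-americans": "African-American",
    "african american": "African-American",
    "mixed": "mixed",
}


class ParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


class ValidationError(ValueError):
    """A parsed record violates a structural invariant."""


def _na(cell: str | None) -> bool:
    return cell is None or cell.strip() in ("", "NA")


def _parse_float(cell: str, row: int, col: str) -> float:
    cell = cell.strip()
    if "," in cell:
        raise ParseError(f"row {row}, column {col!r}: thousands separators not accepted: {cell!r}")
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row}, column {col!r}: malformed numeric cell {cell!r}") from None


def _parse_int(cell: str, row: int, col: str) -> int:
    v = _parse_float(cell, row, col)
    if v != int(v):
        raise ParseError(f"row {row}, column {col!r}: expected an integer, got {cell!r}")
    return int(v)


def _parse_bool(cell: str, row: int, col: str) -> bool:
    norm = cell.strip().lower()
    if norm in ("yes", "true", "1"):
        return True
    if norm in ("no", "false", "0"):
        return False
    raise ParseError(f"row {row}, column {col!r}: expected yes/no, got {cell!r}")


def _norm_ethnicity(cell: str, row: int) -> str:
    key = cell.strip().lower()
    if key not in _ETHNICITY_ALIASES:
        raise ParseError(
            f"row {row}, column 'ethnicity': {cell!r} is not one of {ETHNICITIES}"
        )
    return _ETHNICITY_ALIASES[key]


def _check_proportion(v: float, what: str, study: str) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"study {study!r}: {what} must be in [0,1], got {v}")


@dataclass(frozen=True)
class SnpRaf:
    """One variant carried by a study record: id, named risk allele, frequency."""

    snp_id: str
    risk_allele: str | None = None
    raf: float | None = None


@dataclass(frozen=True)
class CaseControlStudy:
    """One case-control study row (binary outcome).

    Genotype count triples are (hom-risk, het, hom-other); ``raf_control``
    (and the optional ``raf_case``) refer to the named risk allele.  The
    published tables this schema mirrors print a single frequency per study
    without stating the group it refers to; it is stored as the control
    frequency and the ambiguity is documented rather than resolved.
    """

    study_id: str
    ethnicity: str
    snp_id: str
    n_case: int
    n_control: int
    risk_allele: str | None = None
    raf_control: float | None = None
    raf_case: float | None = None
    genotype_counts_case: tuple[float, float, float] | None = None
    genotype_counts_control: tuple[float, float, float] | None = None
    reported_or: float | None = None
    reported_ci: tuple[float, float] | None = None
    hwe_ok: bool | None = None

    def validate(self) -> list[str]:
        """Raise :class:`ValidationError` on hard violations; return warnings."""
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValidationError(f"study {self.study_id!r}: sample sizes must be positive")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {self.study_id!r}: ethnicity {self.ethnicity!r} not in {ETHNICITIES}"
            )
        for raf, what in ((self.raf_control, "raf_control"), (self.raf_case, "raf_case")):
            if raf is not None:
                _check_proportion(raf, what, self.study_id)
        for counts, n, what in (
            (self.genotype_counts_case, self.n_case, "case"),
            (self.genotype_counts_control, self.n_control, "control"),
        ):
            if counts is not None:
                if len(counts) != 3 or any(c < 0 for c in counts):
                    raise ValidationError(
                        f"study {self.study_id!r}: {what} genotype triple must be 3 "
                        "non-negative counts"
                    )
                if not math.isclose(sum(counts), n, rel_tol=0, abs_tol=0.5):
                    raise ValidationError(
                        f"study {self.study_id!r}: {what} genotype counts sum to "
                        f"{sum(counts)}, stated n is {n}"
                    )
        if self.reported_or is not None and self.reported_or <= 0:
            raise ValidationError(f"study {self.study_id!r}: reported OR must be positive")
        if self.reported_ci is not None:
            lo, hi = self.reported_ci
            if not (lo > 0 and hi > 0 and lo < hi):
                raise ValidationError(
                    f"study {self.study_id!r}: CI bounds must be positive with lower < upper"
                )
            if self.reported_or is not None and not (lo < self.reported_or < hi):
                raise ValidationError(
                    f"study {self.study_id!r}: reported OR {self.reported_or} outside its "
                    f"CI ({lo}, {hi})"
                )
        warnings = []
        if not self.has_effect_pathway:
            warnings.append(
                f"study {self.study_id!r}: no usable effect pathway (no counts, no "
                "reported OR, no case+control frequencies)"
            )
        return warnings

    @property
    def has_effect_pathway(self) -> bool:
        return (
            (self.genotype_counts_case is not None and self.genotype_counts_control is not None)
            or (self.reported_or is not None and self.reported_ci is not None)
            or (self.raf_case is not None and self.raf_control is not None)
        )

    @property
    def snps(self) -> tuple[SnpRaf, ...]:
        return (SnpRaf(self.snp_id, self.risk_allele, self.raf_control),)

    def has_snp(self, snp_id: str) -> bool:
        return self.snp_id == snp_id


@dataclass(frozen=True)
class QuantStudy:
    """One quantitative-trait study row (e.g. fasting glucose, mmol/l).

    A record may carry more than one variant (``snps``) when the source
    study characterized several; effect data, when present, refer to the
    primary (first) variant.  ``per_genotype`` is a triple of (n, mean, sd)
    ordered (hom-risk, het, hom-other); ``beta`` is the per-allele slope in
    trait units, accompanied by exactly one of SE, CI, or p.
    """

    study_id: str
    ethnicity: str
    snps: tuple[SnpRaf, ...]
    n: int
    per_genotype: tuple[tuple[int, float, float], ...] | None = None
    beta: float | None = None
    beta_se: float | None = None
    beta_ci: tuple[float, float] | None = None
    beta_p: float | None = None
    hwe_ok: bool | None = None

    def validate(self) -> list[str]:
        if self.n <= 0:
            raise ValidationError(f"study {self.study_id!r}: sample size must be positive")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {self.study_id!r}: ethnicity {self.ethnicity!r} not in {ETHNICITIES}"
            )
        if not self.snps:
            raise ValidationError(f"study {self.study_id!r}: record names no variant")
        for s in self.snps:
            if s.raf is not None:
                _check_proportion(s.raf, f"raf({s.snp_id})", self.study_id)
        if self.per_genotype is not None:
            if len(self.per_genotype) != 3:
                raise ValidationError(
                    f"study {self.study_id!r}: per_genotype must list 3 classes"
                )
            total = sum(g[0] for g in self.per_genotype)
            if total != self.n:
                raise ValidationError(
                    f"study {self.study_id!r}: per-genotype n sum to {total}, stated n "
                    f"is {self.n}"
                )
            for g in self.per_genotype:
                if g[0] > 1 and g[2] <= 0:
                    raise ValidationError(
                        f"study {self.study_id!r}: genotype-class SD must be positive, "
                        f"got {g[2]}"
                    )
        if self.beta is not None:
            have = [
                x is not None for x in (self.beta_se, self.beta_ci, self.beta_p)
            ]
            if sum(have) == 0:
                raise ValidationError(
                    f"study {self.study_id!r}: beta needs one of beta_se, beta_ci, beta_p"
                )
        if self.beta_se is not None and self.beta_se <= 0:
            raise ValidationError(f"study {self.study_id!r}: beta_se must be positive")
        if self.beta_ci is not None and self.beta_ci[0] >= self.beta_ci[1]:
            raise ValidationError(f"study {self.study_id!r}: beta CI must have lower < upper")
        if self.beta_p is not None and not 0 < self.beta_p <= 1:
            raise ValidationError(f"study {self.study_id!r}: beta_p must be in (0,1]")
        warnings = []
        if self.beta is None and self.per_genotype is None:
            warnings.append(
                f"study {self.study_id!r}: characteristics-only record (no beta, no "
                "per-genotype summaries)"
            )
        return warnings

    @property
    def snp_id(self) -> str:
        return self.snps[0].snp_id

    @property
    def raf(self) -> float | None:
        return self.snps[0].raf

    def has_snp(self, snp_id: str) -> bool:
        return any(s.snp_id == snp_id for s in self.snps)

    def raf_of(self, snp_id: str) -> float | None:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s.raf
        raise KeyError(snp_id)


@dataclass
class StudyTable:
    """An ordered, homogeneous collection of study records.

    ``outcome`` is ``"T2D"`` (case-control) or ``"FG"`` (quantitative).
    ``snp_id`` is set when the table has been filtered to one variant.
    """

    records: list
    outcome: str
    snp_id: str | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome not in ("T2D", "FG"):
            raise ValidationError(f"outcome must be 'T2D' or 'FG', got {self.outcome!r}")
        kinds = {type(r) for r in self.records}
        if len(kinds) > 1:
            raise ValidationError(f"mixed record kinds in one table: {kinds}")
        seen: set[str] = set()
        for r in self.records:
            if r.study_id in seen:
                raise ValidationError(f"duplicate study_id {r.study_id!r}")
            seen.add(r.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def for_snp(self, snp_id: str) -> "StudyTable":
        recs = [r for r in self.records if r.has_snp(snp_id)]
        return StudyTable(recs, outcome=self.outcome, snp_id=snp_id)

    @property
    def n_total(self) -> int:
        if self.outcome == "T2D":
            return sum(r.n_case + r.n_control for r in self.records)
        return sum(r.n for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = dataclasses.asdict(r)
            d["snp_ids"] = ";".join(s.snp_id for s in r.snps)
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CC_COLUMNS = [
    "study_id", "ethnicity", "snp_id", "risk_allele", "n_case", "n_control",
    "raf_case", "raf_control",
    "case_hom_risk", "case_het", "case_hom_other",
    "control_hom_risk", "control_het", "control_hom_other",
    "reported_or", "reported_ci_low", "reported_ci_high", "hwe_ok",
]

_Q_COLUMNS = [
    "study_id", "ethnicity", "snp_ids", "risk_alleles", "rafs", "n",
    "beta", "beta_se", "beta_ci_low", "beta_ci_high", "beta_p",
    "hom_risk_n", "hom_risk_mean", "hom_risk_sd",
    "het_n", "het_mean", "het_sd",
    "hom_other_n", "hom_other_mean", "hom_other_sd",
    "hwe_ok",
]


def _read_frame(path, delimiter: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header is missing required columns {missing}")
    return df


def _triple(row, row_no: int, cols: Sequence[str], kinds=(float, float, float)):
    cells = [row[c] for c in cols]
    present = [not _na(c) for c in cells]
    if not any(present):
        return None
    if not all(present):
        raise ParseError(f"row {row_no}: genotype triple {cols} is only partially filled")
    out = []
    for c, col, kind in zip(cells, cols, kinds):
        out.append(
            _parse_int(c, row_no, col) if kind is int else _parse_float(c, row_no, col)
        )
    return tuple(out)


def read_case_control_table(path, delimiter: str = ",") -> StudyTable:
    """Read and validate a case-control study table.

    Missing cells ("NA" or blank) become missing values, never zeros; row
    order is preserved.  Malformed cells raise :class:`ParseError` naming
    the row and column; invariant violations raise :class:`ValidationError`
    naming the record.
    """
    df = _read_frame(path, delimiter, ["study_id", "ethnicity", "snp_id", "n_case", "n_control"])
    records, warnings = [], []
    for i, row in df.iterrows():
        row_no = i + 2  # header is line 1
        ci = None
        if not _na(row.get("reported_ci_low")) and not _na(row.get("reported_ci_high")):
            ci = (
                _parse_float(row["reported_ci_low"], row_no, "reported_ci_low"),
                _parse_float(row["reported_ci_high"], row_no, "reported_ci_high"),
            )

        def opt_float(col: str) -> float | None:
            cell = row.get(col)
            return None if _na(cell) else _parse_float(cell, row_no, col)

        rec = CaseControlStudy(
            study_id=row["study_id"].strip(),
            ethnicity=_norm_ethnicity(row["ethnicity"], row_no),
            snp_id=row["snp_id"].strip(),
            risk_allele=None if _na(row.get("risk_allele")) else row["risk_allele"].strip(),
            n_case=_parse_int(row["n_case"], row_no, "n_case"),
            n_control=_parse_int(row["n_control"], row_no, "n_control"),
            raf_case=opt_float("raf_case"),
            raf_control=opt_float("raf_control"),
            genotype_counts_case=_triple(
                row, row_no, ["case_hom_risk", "case_het", "case_hom_other"]
            ),
            genotype_counts_control=_triple(
                row, row_no, ["control_hom_risk", "control_het", "control_hom_other"]
            ),
            reported_or=opt_float("reported_or"),
            reported_ci=ci,
            hwe_ok=None if _na(row.get("hwe_ok")) else _parse_bool(row["hwe_ok"], row_no, "hwe_ok"),
        )
        warnings.extend(rec.validate())
        records.append(rec)
    return StudyTable(records, outcome="T2D", warnings=warnings)


def read_quant_table(path, delimiter: str = ",") -> StudyTable:
    """Read and validate a quantitative-trait study table.

    Beta-only rows and per-genotype rows are both accepted; rows listing
    several variants use ``;``-separated ``snp_ids``/``risk_alleles``/``rafs``.
    """
    df = _read_frame(path, delimiter, ["study_id", "ethnicity", "snp_ids", "n"])
    records, warnings = [], []
    for i, row in df.iterrows():
        row_no = i + 2

        def opt_float(col: str) -> float | None:
            cell = row.get(col)
            return None if _na(cell) else _parse_float(cell, row_no, col)

        snp_ids = [s.strip() for s in row["snp_ids"].split(";") if s.strip()]
        alleles = (
            [None] * len(snp_ids)
            if _na(row.get("risk_alleles"))
            else [None if _na(a) else a.strip() for a in row["risk_alleles"].split(";")]
        )
        rafs_cell = row.get("rafs")
        rafs = (
            [None] * len(snp_ids)
            if _na(rafs_cell)
            else [
                None if _na(c) else _parse_float(c, row_no, "rafs")
                for c in rafs_cell.split(";")
            ]
        )
        if len(alleles) != len(snp_ids) or len(rafs) != len(snp_ids):
            raise ParseError(
                f"row {row_no}: snp_ids/risk_alleles/rafs lists have different lengths"
            )
        snps = tuple(SnpRaf(s, a, f) for s, a, f in zip(snp_ids, alleles, rafs))

        per_genotype = None
        triples = [
            _triple(row, row_no, [f"{g}_n", f"{g}_mean", f"{g}_sd"], (int, float, float))
            for g in ("hom_risk", "het", "hom_other")
        ]
        if any(t is not None for t in triples):
            if any(t is None for t in triples):
                raise ParseError(f"row {row_no}: per-genotype summaries only partially filled")
            per_genotype = tuple(triples)

        ci = None
        if not _na(row.get("beta_ci_low")) and not _na(row.get("beta_ci_high")):
            ci = (
                _parse_float(row["beta_ci_low"], row_no, "beta_ci_low"),
                _parse_float(row["beta_ci_high"], row_no, "beta_ci_high"),
            )
        rec = QuantStudy(
            study_id=row["study_id"].strip(),
            ethnicity=_norm_ethnicity(row["ethnicity"], row_no),
            snps=snps,
            n=_parse_int(row["n"], row_no, "n"),
            per_genotype=per_genotype,
            beta=opt_float("beta"),
            beta_se=opt_float("beta_se"),
            beta_ci=ci,
            beta_p=opt_float("beta_p"),
            hwe_ok=None if _na(row.get("hwe_ok")) else _parse_bool(row["hwe_ok"], row_no, "hwe_ok"),
        )
        warnings.extend(rec.validate())
        records.append(rec)
    return StudyTable(records, outcome="FG", warnings=warnings)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "yes" if v else "no"
    if isinstance(v, float):
        return repr(v)  # shortest round-trip representation
    return str(v)


def _write_rows(path, header: list[str], rows: Iterable[list], delimiter: str) -> None:
    buf = _io.StringIO()
    buf.write(delimiter.join(header) + "\n")
    for row in rows:
        buf.write(delimiter.join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_case_control_table(table: StudyTable, path, delimiter: str = ",") -> None:
    rows = []
    for r in table:
        cc = r.genotype_counts_case or (None, None, None)
        ct = r.genotype_counts_control or (None, None, None)
        ci = r.reported_ci or (None, None)
        rows.append([
            r.study_id, r.ethnicity, r.snp_id, r.risk_allele, r.n_case, r.n_control,
            r.raf_case, r.raf_control, *cc, *ct, r.reported_or, *ci, r.hwe_ok,
        ])
    _write_rows(path, _CC_COLUMNS, rows, delimiter)


def write_quant_table(table: StudyTable, path, delimiter: str = ",") -> None:
    rows = []
    for r in table:
        pg = r.per_genotype or ((None,) * 3,) * 3
        ci = r.beta_ci or (None, None)
        rows.append([
            r.study_id, r.ethnicity,
            ";".join(s.snp_id for s in r.snps),
            ";".join(_fmt(s.risk_allele) for s in r.snps),
            ";".join(_fmt(s.raf) for s in r.snps),
            r.n, r.beta, r.beta_se, *ci, r.beta_p,
            *pg[0], *pg[1], *pg[2], r.hwe_ok,
        ])
    _write_rows(path, _Q_COLUMNS, rows, delimiter)


_RESULT_COLUMNS = [
    "snp", "subgroup", "model", "k", "n", "estimate", "ci_low", "ci_high",
    "p", "Q", "I2", "I2_ci", "H2", "tau2",
]


def write_results_table(results, path, delimiter: str = ",") -> None:
    """Write pooled results as delimited text.

    ``results`` is a non-empty collection of :class:`~genemeta.meta.MetaResult`
    (or any object with a ``to_row()`` returning the column dict).  Floats
    use their shortest round-trip representation, so the table re-reads to
    full stored precision and a write/read/write cycle is byte-identical.
    """
    results = list(results)
    if not results:
        raise ValueError("results collection is empty")
    rows = []
    for r in results:
        d = r if isinstance(r, dict) else r.to_row()
        rows.append([d.get(c) for c in _RESULT_COLUMNS])
    _write_rows(path, _RESULT_COLUMNS, rows, delimiter)


def read_results_table(path, delimiter: str = ",") -> list[dict]:
    """Read back a results table written by :func:`write_results_table`."""
    df = _read_frame(path, delimiter, _RESULT_COLUMNS)
    out = []
    for i, row in df.iterrows():
        row_no = i + 2
        d: dict = {}
        for c in _RESULT_COLUMNS:
            cell = row[c]
            if c in ("snp", "subgroup", "model", "I2_ci"):
                d[c] = None if _na(cell) else cell
            elif c in ("k", "n"):
                d[c] = None if _na(cell) else _parse_int(cell, row_no, c)
            else:
                d[c] = None if _na(cell) else _parse_float(cell, row_no, c)
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("genemeta").joinpath("data", name)


def load_t2d_studies() -> StudyTable:
    """Case-control characteristics of the published G6PC2/T2D studies."""
    with resources.as_file(_data_path("g6pc2_t2d_studies.csv")) as p:
        return read_case_control_table(p)


def load_fg_studies() -> StudyTable:
    """Quantitative-trait characteristics of the published G6PC2/FG studies."""
    with resources.as_file(_data_path("g6pc2_fg_studies.csv")) as p:
        return read_quant_table(p)
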