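"""Tabular data model and I/O for SILAC acetylation quantification.

The pipeline consumes processed search-engine-style tables, never raw
spectra.  Every table is plain TSV with a header row, ``.`` decimals and
UTF-8 text; missing values are empty fields.  Records are validated on
read and rows that violate an invariant are rejected with a diagnostic
carrying the (1-based) data-row number.

SILAC ratio orientation is fixed throughout the package as
light(treated) / heavy(untreated).  Tables that store the inverse can be
read with ``ratio_is_heavy_over_light=True``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO

COMPARTMENTS = ("mitochondrion", "cytoplasm", "nucleus", "other")

AC_MARKER = "(ac)"


class TableFormatError(ValueError):
    """The file as a whole cannot be interpreted (missing column, empty file...)."""


@dataclass(frozen=True)
class RowIssue:
    """Diagnostic for a single rejected row."""

    row: int  # 1-based data row index (header excluded)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.message}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinQuant:
    """Protein-level quantification.

    ``total_intensity`` is the summed MS intensity over the protein's
    peptides; ``silac_ratio`` compares the two SILAC channels (L/H);
    ``n_observable_peptides`` is the count of theoretically observable
    tryptic peptides used for iBAQ; ``localizations`` is the set of
    subcellular compartments the protein is annotated to.
    """

    protein_id: str
    total_intensity: float
    silac_ratio: float | None = None
    localizations: frozenset = frozenset()
    sequence: str | None = None
    n_observable_peptides: int | None = None

    @property
    def ibaq(self) -> float | None:
        """Intensity-based absolute quantification: intensity per observable peptide."""
        if self.n_observable_peptides is None:
            return None
        return self.total_intensity / self.n_observable_peptides

    def validate(self) -> None:
        if not self.protein_id:
            raise ValueError("empty protein_id")
        if not (self.total_intensity >= 0):
            raise ValueError(f"total_intensity must be >= 0, got {self.total_intensity}")
        if self.silac_ratio is not None and not (self.silac_ratio > 0):
            raise ValueError(f"silac_ratio must be > 0, got {self.silac_ratio}")
        if self.n_observable_peptides is not None and self.n_observable_peptides < 1:
            raise ValueError("n_observable_peptides must be >= 1 when present")
        unknown = set(self.localizations) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartment labels: {sorted(unknown)}")


@dataclass
class SiteQuant:
    """One acetylation site: identity plus light/heavy channel quantification.

    ``position`` is the 1-based lysine residue index on the protein;
    ``peptide`` carries the modification as ``(ac)`` immediately after the
    modified residue.  ``naturally_occurring`` marks sites identified in an
    untreated control or a prior site list, as opposed to sites created by
    the chemical treatment itself.
    """

    protein_id: str
    position: int
    peptide: str
    light_intensity: float
    heavy_intensity: float | None = None
    silac_ratio: float | None = None
    naturally_occurring: bool = True

    def validate(self) -> None:
        if not self.protein_id:
            raise ValueError("empty protein_id")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if AC_MARKER not in self.peptide:
            raise ValueError(f"peptide {self.peptide!r} lacks an {AC_MARKER} marker")
        if not (self.light_intensity >= 0):
            raise ValueError(f"light_intensity must be >= 0, got {self.light_intensity}")
        if self.heavy_intensity is not None and not (self.heavy_intensity >= 0):
            raise ValueError(f"heavy_intensity must be >= 0, got {self.heavy_intensity}")
        if self.silac_ratio is not None:
            if not (self.silac_ratio > 0):
                raise ValueError(f"silac_ratio must be > 0, got {self.silac_ratio}")
            if self.heavy_intensity is None:
                raise ValueError("silac_ratio present without an observed heavy channel")


@dataclass
class AquaRecord:
    """Intensities for one peptide quantified against heavy spiked standards.

    The acetylated and the unmodified (corresponding) form are each measured
    in the light channel next to a heavy-labeled standard of known spiked
    amount, giving absolute amounts and hence site occupancy.
    """

    peptide: str
    ac_light_intensity: float
    ac_standard_intensity: float
    unmod_light_intensity: float
    unmod_standard_intensity: float
    ac_spike_amount: float
    unmod_spike_amount: float

    def validate(self) -> None:
        for f in fields(self):
            if f.name == "peptide":
                continue
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"{f.name} must be > 0, got {v}")


@dataclass
class TmtRecord:
    """Reporter-ion intensities for one peptide in a multiplexed TMT run.

    ``parent_purity`` is the fraction of the total ion current in the
    isolation window contributed by the targeted parent ion; impure spectra
    are filtered before quantification.
    """

    peptide: str
    is_acetylated: bool
    reporter_intensities: tuple
    parent_purity: float

    def validate(self) -> None:
        if any(v < 0 for v in self.reporter_intensities):
            raise ValueError("reporter intensities must be >= 0")
        if not (0.0 <= self.parent_purity <= 1.0):
            raise ValueError(f"parent_purity must lie in [0, 1], got {self.parent_purity}")


@dataclass
class StoichEstimate:
    """Per-site stoichiometry estimate.

    Exactly one of ``ratio`` (both channels observed) or ``min_ratio``
    (heavy channel below detection; conservative lower bound on the ratio)
    is set.  ``bound_percent`` is the upper bound on initial occupancy in
    percent; insensitive sites carry the ``>1%`` flag instead of a numeric
    bound.  ``i_over_ibaq_a`` is the abundance-corrected acetyl-peptide
    intensity computed from untreated-channel quantities.
    """

    protein_id: str
    position: int
    peptide: str
    ratio: float | None = None
    min_ratio: float | None = None
    sensitivity_class: str = "no_ratio"
    bound_percent: float | None = None
    flag: str | None = None
    i_over_ibaq_a: float | None = None

    def validate(self) -> None:
        if self.sensitivity_class not in ("insensitive", "sensitive", "no_ratio"):
            raise ValueError(f"unknown sensitivity_class {self.sensitivity_class!r}")
        if self.bound_percent is not None and not (self.bound_percent > 0):
            raise ValueError("bound_percent must be > 0 when present")
        if self.ratio is not None and self.min_ratio is not None:
            raise ValueError("ratio and min_ratio are mutually exclusive")
        if self.ratio is not None and (self.ratio < 2) != (self.sensitivity_class == "insensitive"):
            raise ValueError("sensitivity_class inconsistent with ratio")


class TableReadResult(NamedTuple):
    """Records parsed from a table plus per-row rejection diagnostics."""

    records: list
    issues: list


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _open_rows(path, required: Sequence[str], column_map: Mapping[str, str] | None):
    """Yield (row_number, dict) for a TSV file, checking required columns.

    ``column_map`` maps canonical field names to the file's column names.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise TableFormatError(f"{path}: empty file")
        colmap = dict(column_map or {})
        rename = {colmap.get(name, name): name for name in set(required) | set(colmap)}
        have = set(header)
        for canonical in required:
            if colmap.get(canonical, canonical) not in have:
                raise TableFormatError(f"{path}: missing required column {canonical!r}")
        rows = []
        for i, raw in enumerate(reader, start=1):
            row = {rename.get(k, k): (v.strip() if v is not None else "") for k, v in raw.items() if k is not None}
            rows.append((i, row))
    return rows


def _opt_float(value: str, name: str) -> float | None:
    if value == "":
        return None
    try:
        x = float(value)
    except ValueError as exc:
        raise ValueError(f"non-numeric {name}: {value!r}") from exc
    if math.isnan(x):
        return None
    return x


def _req_float(value: str, name: str) -> float:
    x = _opt_float(value, name)
    if x is None:
        raise ValueError(f"missing {name}")
    return x


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _opt_bool(value: str, name: str, default: bool) -> bool:
    if value == "":
        return default
    v = value.lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"non-boolean {name}: {value!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_site_table(
    path,
    column_map: Mapping[str, str] | None = None,
    ratio_is_heavy_over_light: bool = False,
) -> TableReadResult:
    """Read an acetylation-site table.

    Required columns: ``protein_id``, ``position``, ``peptide``,
    ``light_intensity``; optional: ``heavy_intensity``, ``silac_ratio``,
    ``naturally_occurring``.  When ``silac_ratio`` is absent and both
    channels are observed and positive it is computed as light/heavy.
    """
    required = ("protein_id", "position", "peptide", "light_intensity")
    records: list[SiteQuant] = []
    issues: list[RowIssue] = []
    for i, row in _open_rows(path, required, column_map):
        try:
            ratio = _opt_float(row.get("silac_ratio", ""), "silac_ratio")
            if ratio is not None and ratio_is_heavy_over_light:
                ratio = 1.0 / ratio
            heavy = _opt_float(row.get("heavy_intensity", ""), "heavy_intensity")
            light = _req_float(row.get("light_intensity", ""), "light_intensity")
            if ratio is None and heavy is not None and heavy > 0 and light > 0:
                ratio = light / heavy
            rec = SiteQuant(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                peptide=row["peptide"],
                light_intensity=light,
                heavy_intensity=heavy,
                silac_ratio=ratio,
                naturally_occurring=_opt_bool(
                    row.get("naturally_occurring", ""), "naturally_occurring", True
                ),
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            issues.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, issues)


def read_protein_table(
    path,
    column_map: Mapping[str, str] | None = None,
    ratio_is_heavy_over_light: bool = False,
) -> TableReadResult:
    """Read a protein quantification table.

    Required columns: ``protein_id``, ``total_intensity``; optional:
    ``silac_ratio``, ``localizations`` (semicolon-separated compartment
    labels), ``sequence``, ``n_observable_peptides``.
    """
    required = ("protein_id", "total_intensity")
    records: list[ProteinQuant] = []
    issues: list[RowIssue] = []
    for i, row in _open_rows(path, required, column_map):
        try:
            ratio = _opt_float(row.get("silac_ratio", ""), "silac_ratio")
            if ratio is not None and ratio_is_heavy_over_light:
                ratio = 1.0 / ratio
            locs = frozenset(
                tok.strip() for tok in row.get("localizations", "").split(";") if tok.strip()
            )
            n_obs_raw = row.get("n_observable_peptides", "")
            rec = ProteinQuant(
                protein_id=row["protein_id"],
                total_intensity=_req_float(row.get("total_intensity", ""), "total_intensity"),
                silac_ratio=ratio,
                localizations=locs,
                sequence=row.get("sequence") or None,
                n_observable_peptides=int(n_obs_raw) if n_obs_raw else None,
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            issues.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, issues)


def read_intensity_list(path, column: str = "intensity") -> list[float]:
    """Read a one-column TSV of peptide intensities (heavy-channel evidence)."""
    values: list[float] = []
    for i, row in _open_rows(path, (column,), None):
        values.append(_req_float(row[column], column))
    return values


def read_aqua_table(path, column_map: Mapping[str, str] | None = None) -> TableReadResult:
    """Read an AQUA intensity table (one row per peptide)."""
    required = (
        "peptide",
        "ac_light_intensity",
        "ac_standard_intensity",
        "unmod_light_intensity",
        "unmod_standard_intensity",
        "ac_spike_amount",
        "unmod_spike_amount",
    )
    records: list[AquaRecord] = []
    issues: list[RowIssue] = []
    for i, row in _open_rows(path, required, column_map):
        try:
            rec = AquaRecord(
                peptide=row["peptide"],
                **{name: _req_float(row[name], name) for name in required[1:]},
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            issues.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, issues)


def read_tmt_table(path, column_map: Mapping[str, str] | None = None) -> TableReadResult:
    """Read a TMT reporter table.

    ``reporter_intensities`` is a semicolon-separated intensity vector.
    """
    required = ("peptide", "is_acetylated", "reporter_intensities", "parent_purity")
    records: list[TmtRecord] = []
    issues: list[RowIssue] = []
    for i, row in _open_rows(path, required, column_map):
        try:
            reporters = tuple(
                _req_float(tok, "reporter_intensity")
                for tok in row["reporter_intensities"].split(";")
                if tok.strip()
            )
            rec = TmtRecord(
                peptide=row["peptide"],
                is_acetylated=_opt_bool(row["is_acetylated"], "is_acetylated", False),
                reporter_intensities=reporters,
                parent_purity=_req_float(row["parent_purity"], "parent_purity"),
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            issues.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, issues)


def read_localization_map(path) -> dict:
    """Read protein → compartment-set map (columns protein_id, localizations)."""
    result: dict[str, frozenset] = {}
    for i, row in _open_rows(path, ("protein_id", "localizations"), None):
        locs = frozenset(t.strip() for t in row["localizations"].split(";") if t.strip())
        result[row["protein_id"]] = locs
    return result


def read_annotation_map(path) -> dict:
    """Read protein → term-set map (columns protein_id, terms; terms ';'-separated).

    Proteins listed with an empty term set are rejected.
    """
    result: dict[str, frozenset] = {}
    for i, row in _open_rows(path, ("protein_id", "terms"), None):
        terms = frozenset(t.strip() for t in row["terms"].split(";") if t.strip())
        if not terms:
            raise TableFormatError(f"{path}: row {i}: empty term set for {row['protein_id']!r}")
        result[row["protein_id"]] = terms
    return result


def read_fasta(path) -> dict:
    """Read a FASTA file into protein_id → sequence.

    The identifier is the first whitespace token of the header line.
    Duplicate identifiers and empty files are format errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise TableFormatError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise TableFormatError(f"{path}: no FASTA records found")
    return sequences


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


ESTIMATE_COLUMNS = (
    "protein_id",
    "position",
    "peptide",
    "ratio",
    "min_ratio",
    "sensitivity_class",
    "bound_percent",
    "flag",
    "i_over_ibaq_a",
)


def write_estimates(path, estimates: Iterable[StoichEstimate]) -> None:
    """Write stoichiometry estimates as TSV; round-trips losslessly via
    :func:`read_estimates` (floats serialized at full repr precision)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ESTIMATE_COLUMNS)
        for est in estimates:
            est.validate()
            writer.writerow([_fmt(getattr(est, col)) for col in ESTIMATE_COLUMNS])


def read_estimates(path) -> TableReadResult:
    """Read a stoichiometry-estimate table written by :func:`write_estimates`."""
    records: list[StoichEstimate] = []
    issues: list[RowIssue] = []
    for i, row in _open_rows(path, ("protein_id", "position", "peptide", "sensitivity_class"), None):
        try:
            rec = StoichEstimate(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                peptide=row["peptide"],
                ratio=_opt_float(row.get("ratio", ""), "ratio"),
                min_ratio=_opt_float(row.get("min_ratio", ""), "min_ratio"),
                sensitivity_class=row["sensitivity_class"],
                bound_percent=_opt_float(row.get("bound_percent", ""), "bound_percent"),
                flag=row.get("flag") or None,
                i_over_ibaq_a=_opt_float(row.get("i_over_ibaq_a", ""), "i_over_ibaq_a"),
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            issues.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, issues)


SITE_COLUMNS = (
    "protein_id",
    "position",
    "peptide",
    "light_intensity",
    "heavy_intensity",
    "silac_ratio",
    "naturally_occurring",
)

PROTEIN_COLUMNS = (
    "protein_id",
    "total_intensity",
    "silac_ratio",
    "localizations",
    "sequence",
    "n_observable_peptides",
)


def write_site_table(path, sites: Iterable[SiteQuant]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS)
        for s in sites:
            writer.writerow([_fmt(getattr(s, col)) for col in SITE_COLUMNS])


def write_protein_table(path, proteins: Iterable[ProteinQuant]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROTEIN_COLUMNS)
        for p in proteins:
            row = []
            for col in PROTEIN_COLUMNS:
                v = getattr(p, col)
                if col == "localizations":
                    v = ";".join(sorted(v))
                row.append(_fmt(v))
            writer.writerow(row)


def write_intensity_list(path, intensities: Iterable[float], column: str = "intensity") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([column])
        for v in intensities:
            writer.writerow([_fmt(float(v))])
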