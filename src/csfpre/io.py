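"""Reading and writing protein-report tables, sample metadata and run configuration.

The pipeline's lingua franca is the :class:`AbundanceMatrix`: a proteins ×
samples table of non-negative, linear-scale abundances with explicit missing
values (``NaN``) and per-sample role metadata (:class:`SampleMeta`).  Readers
are thin column-name translations over the tab-separated "protein report"
exports of common quantification tools; no vendor binary format is parsed.

Missing values propagate: any downstream ratio with a missing operand is
missing.  Abundances are linear scale on input; log transforms are internal to
the operations that need them.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "AbundanceMatrix",
    "RunConfig",
    "ProteinReportError",
    "ConfigError",
    "DIALECTS",
    "read_protein_report",
    "write_protein_report",
    "read_sample_meta",
    "write_sample_meta",
    "load_config",
]

ROLES = ("reference", "spiked", "rcg_point", "patient_fluid")
FLUIDS = ("CSF", "plasma")

#: Strings treated as explicit missing markers in report cells.
MISSING_MARKERS = frozenset({"", "na", "nan", "n/a", "none", "null", "#n/a", "missing"})


class ProteinReportError(ValueError):
    """A protein report file violates the documented format."""


class ConfigError(ValueError):
    """A run configuration file is invalid."""


@dataclass(frozen=True)
class SampleMeta:
    """Role metadata for one sample column.

    The role determines which optional fields must be present:

    * ``reference`` — none.
    * ``spiked`` — ``spike_fraction`` (blood volume fraction in [0, 1]);
      ``centrifuged`` optional.
    * ``rcg_point`` — ``rcg_point`` (collection point index, 1 = lumbar-most).
    * ``patient_fluid`` — ``patient_id`` and ``fluid`` (CSF or plasma).
    """

    sample_id: str
    role: str
    spike_fraction: float | None = None
    centrifuged: bool | None = None
    rcg_point: int | None = None
    patient_id: str | None = None
    fluid: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if (self.spike_fraction is not None) != (self.role == "spiked"):
            raise ValueError(
                f"sample {self.sample_id!r}: spike_fraction must be present "
                "iff role is 'spiked'"
            )
        if self.spike_fraction is not None and not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError(f"sample {self.sample_id!r}: spike_fraction outside [0, 1]")
        if (self.rcg_point is not None) != (self.role == "rcg_point"):
            raise ValueError(
                f"sample {self.sample_id!r}: rcg_point must be present "
                "iff role is 'rcg_point'"
            )
        if self.rcg_point is not None and (
            self.rcg_point != int(self.rcg_point) or self.rcg_point < 1
        ):
            raise ValueError(f"sample {self.sample_id!r}: rcg_point must be an integer >= 1")
        if self.role == "patient_fluid":
            if self.patient_id is None or self.fluid is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: patient_id and fluid required "
                    "for role 'patient_fluid'"
                )
            if self.fluid not in FLUIDS:
                raise ValueError(f"sample {self.sample_id!r}: fluid must be one of {FLUIDS}")

    @property
    def condition(self) -> str:
        """Condition label; duplicate channels of one condition share it."""
        if self.role == "reference":
            return "reference"
        if self.role == "rcg_point":
            return f"rcg_{self.rcg_point}"
        if self.role == "spiked":
            tag = f"spike_{self.spike_fraction:g}"
            if self.centrifuged is False:
                tag += "_nc"
            return tag
        return f"{self.patient_id}_{self.fluid}"


@dataclass
class AbundanceMatrix:
    """Proteins × samples abundance table with sample-role metadata.

    Parameters
    ----------
    values
        Float DataFrame indexed by unique protein accession, one column per
        sample id, ``NaN`` marking missing values.  All finite values must be
        non-negative (linear-scale abundances).
    sample_meta
        Mapping sample id → :class:`SampleMeta`, in column order.
    peptide_counts
        Optional count of unique peptides used for quantification, either per
        (protein, sample) (DataFrame aligned to ``values``) or per protein
        (Series, one experiment-wide count).
    """

    values: pd.DataFrame
    sample_meta: dict[str, SampleMeta]
    peptide_counts: pd.DataFrame | pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ProteinReportError(f"duplicate accessions: {dups}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "accession"
        if list(self.values.columns) != list(self.sample_meta):
            raise ValueError(
                "sample_meta keys must match value columns in order: "
                f"{list(self.values.columns)} vs {list(self.sample_meta)}"
            )
        for sid, meta in self.sample_meta.items():
            if meta.sample_id != sid:
                raise ValueError(f"sample_meta key {sid!r} != meta.sample_id {meta.sample_id!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be >= 0 or missing")

    @property
    def accessions(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def meta(self, sample_id: str) -> SampleMeta:
        return self.sample_meta[sample_id]

    def copy(self) -> "AbundanceMatrix":
        pc = None if self.peptide_counts is None else self.peptide_counts.copy()
        return AbundanceMatrix(self.values.copy(), dict(self.sample_meta), pc)


@dataclass(frozen=True)
class Dialect:
    """Column-name conventions of a protein-report export."""

    accession_column: str
    sample_prefix: str = ""


#: Supported report dialects.  A dialect is a documented column-name
#: translation only; quantitative content is identical across dialects.
DIALECTS: dict[str, Dialect] = {
    "generic": Dialect("accession"),
    "progenesis": Dialect("Accession"),
    "spectrummill": Dialect("accession_number"),
    "pd": Dialect("Accession", sample_prefix="Abundance: "),
}

_PEPTIDE_PREFIX = "n_unique_peptides_"
_PEPTIDE_GLOBAL = "n_unique_peptides"
_NAME_COLUMN = "protein_name"


def _read_table(path: Path, sheet: str | int | None) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=0 if sheet is None else sheet, dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def read_protein_report(
    path: str | Path,
    dialect: str = "generic",
    meta: Mapping[str, SampleMeta] | None = None,
    sheet: str | int | None = None,
) -> AbundanceMatrix:
    """Read a protein report into a validated :class:`AbundanceMatrix`.

    Every sample declared in ``meta`` must appear as a column (after stripping
    the dialect's sample prefix).  Cells that do not parse as numbers become
    missing; their count is logged as a warning.  No data row is silently
    dropped: a duplicate accession raises rather than being merged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in DIALECTS:
        raise ProteinReportError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    if meta is None or not meta:
        raise ValueError("sample metadata mapping is required")
    d = DIALECTS[dialect]
    raw = _read_table(path, sheet)
    if d.accession_column not in raw.columns:
        raise ProteinReportError(
            f"{path}: missing accession column {d.accession_column!r} (dialect {dialect!r})"
        )
    raw = raw.rename(columns={d.accession_column: "accession"})
    if d.sample_prefix:
        raw = raw.rename(
            columns={
                c: c[len(d.sample_prefix):]
                for c in raw.columns
                if c.startswith(d.sample_prefix)
            }
        )
    accessions = raw["accession"].astype(str)
    dup = accessions[accessions.duplicated()].unique().tolist()
    if dup:
        raise ProteinReportError(f"{path}: duplicate accession rows: {dup}")

    absent = [sid for sid in meta if sid not in raw.columns]
    if absent:
        raise ProteinReportError(f"{path}: samples declared in metadata but absent: {absent}")

    values = pd.DataFrame(index=pd.Index(accessions, name="accession"))
    n_unparseable = 0
    for sid in meta:
        col = raw[sid]
        parsed = pd.to_numeric(col, errors="coerce")
        newly_missing = parsed.isna() & col.notna() & ~col.str.strip().str.lower().isin(MISSING_MARKERS)
        n_unparseable += int(newly_missing.sum())
        values[sid] = parsed.to_numpy()
    if n_unparseable or values.isna().any().any():
        n_missing = int(values.isna().sum().sum())
        logger.warning(
            "%s: %d missing abundance cells (%d unparseable)", path, n_missing, n_unparseable
        )

    peptide_counts: pd.DataFrame | pd.Series | None = None
    per_sample = {
        c[len(_PEPTIDE_PREFIX):]: c for c in raw.columns if c.startswith(_PEPTIDE_PREFIX)
    }
    if per_sample:
        peptide_counts = pd.DataFrame(
            {
                sid: pd.to_numeric(raw[col], errors="coerce").to_numpy()
                for sid, col in per_sample.items()
            },
            index=values.index,
        )
    elif _PEPTIDE_GLOBAL in raw.columns:
        peptide_counts = pd.Series(
            pd.to_numeric(raw[_PEPTIDE_GLOBAL], errors="coerce").to_numpy(),
            index=values.index,
            name=_PEPTIDE_GLOBAL,
        )

    return AbundanceMatrix(values, {sid: meta[sid] for sid in meta}, peptide_counts)


def write_protein_report(matrix: AbundanceMatrix, path: str | Path) -> Path:
    """Write a matrix as a generic-dialect TSV (missing values as empty cells)."""
    path = Path(path)
    out = matrix.values.copy()
    if isinstance(matrix.peptide_counts, pd.DataFrame):
        for sid in matrix.peptide_counts.columns:
            out[_PEPTIDE_PREFIX + sid] = matrix.peptide_counts[sid]
    elif isinstance(matrix.peptide_counts, pd.Series):
        out[_PEPTIDE_GLOBAL] = matrix.peptide_counts
    out.to_csv(path, sep="\t", na_rep="")
    return path


_META_COLUMNS = [
    "sample_id", "role", "spike_fraction", "centrifuged", "rcg_point", "patient_id", "fluid",
]


def write_sample_meta(meta: Mapping[str, SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for m in meta.values():
        rows.append(
            {
                "sample_id": m.sample_id,
                "role": m.role,
                "spike_fraction": m.spike_fraction,
                "centrifuged": m.centrifuged,
                "rcg_point": m.rcg_point,
                "patient_id": m.patient_id,
                "fluid": m.fluid,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read a sample-metadata TSV written by :func:`write_sample_meta`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "role") if c not in df.columns]
    if missing:
        raise ProteinReportError(f"{path}: metadata lacks columns {missing}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        def _get(key: str) -> str | None:
            v = row.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                return None
            return str(v)

        centrifuged = _get("centrifuged")
        spike = _get("spike_fraction")
        point = _get("rcg_point")
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            role=str(row["role"]),
            spike_fraction=float(spike) if spike is not None else None,
            centrifuged=None if centrifuged is None else centrifuged.lower() in {"true", "1", "yes"},
            rcg_point=int(float(point)) if point is not None else None,
            patient_id=_get("patient_id"),
            fluid=_get("fluid"),
        )
        out[meta.sample_id] = meta
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with the study's default thresholds.

    Fold-change thresholds are magnitudes on the linear scale; the R² limits
    bound the linearity bands of the gradient classification; ``band_low`` /
    ``band_high`` delimit the plasma/CSF equal-protein ratio bands.
    """

    fc_affected: float = 1.5
    fc_unaffected: float = 1.2
    r2_low: float = 0.3
    r2_high: float = 0.7
    suppression_fc: float = 2.0
    band_low: float = 0.2
    band_high: float = 0.4
    noise_cv: float = 0.20
    seed: int | None = None
    depletion_list: tuple[str, ...] = ()
    dialect: str = "generic"
    xlsx_sheet: str | None = None

    def __post_init__(self) -> None:
        bad: list[str] = []
        if not self.fc_unaffected > 1.0:
            bad.append("fc_unaffected")
        if not self.fc_affected > self.fc_unaffected:
            bad.append("fc_affected")
        if not 0.0 <= self.r2_low <= self.r2_high <= 1.0:
            bad.append("r2_low/r2_high")
        if not self.suppression_fc > 1.0:
            bad.append("suppression_fc")
        if not 0.0 < self.band_low < self.band_high:
            bad.append("band_low/band_high")
        if self.noise_cv < 0.0:
            bad.append("noise_cv")
        if self.dialect not in DIALECTS:
            bad.append("dialect")
        if bad:
            raise ConfigError(f"out-of-range configuration keys: {bad}")

    def require_seed(self) -> int:
        """Return the seed; simulation commands refuse to run without one."""
        if self.seed is None:
            raise ConfigError("an explicit seed is required for simulation commands")
        return int(self.seed)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML key/value configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys: {unknown}")
    if "depletion_list" in raw:
        raw["depletion_list"] = tuple(raw["depletion_list"])
    return RunConfig(**raw)
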