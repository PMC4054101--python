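"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are plain TSV/CSV (delimiter chosen by file extension, never
sniffed). Readers validate strictly and never silently coerce or drop data;
the only data-altering behaviour is the explicit ``missing_policy`` of
:func:`read_intensity_matrix`.

Conventions
-----------
* Intensity matrices are phosphopeptide x sample: first column holds peptide
  identifiers, the header row holds sample identifiers. Identifiers are
  treated as opaque keys; the display convention in real data is
  ``GENE_p<residue><position>_z<charge>`` (for example ``NBEAL_pT225_z2``).
* Residue positions are 1-based, matching the biological convention for
  phosphosite names.
* Floats are written with 12 significant digits, so write-then-read
  round-trips are identity up to that precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DISEASES",
    "FormatError",
    "IntensityMatrix",
    "SampleMeta",
    "ViabilityTable",
    "PhosphoSiteAnnotation",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "read_viability",
    "write_viability",
    "read_site_annotations",
    "write_site_annotations",
    "read_fasta",
    "write_fasta",
    "validate_bundle",
]

#: Disease labels recognised in sample metadata.
DISEASES = ("AML", "lymphoma", "myeloma", "other")

_FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """A file or in-memory table violates the format contract."""


def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    raise FormatError(f"unsupported table extension {suffix!r} for {path} (use .tsv or .csv)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityMatrix:
    """Non-negative phosphopeptide x sample intensity table.

    ``data`` is indexed by peptide id with sample ids as columns. Values are
    arbitrary MS intensity units; NaN marks a missing measurement.
    ``provenance`` records the processing steps already applied.
    """

    data: pd.DataFrame
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate peptide ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if not all(np.issubdtype(t, np.number) for t in df.dtypes):
            bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
            raise FormatError(f"non-numeric sample columns: {bad}")
        values = df.to_numpy(dtype=float)
        if np.any(values[np.isfinite(values)] < 0):
            r, c = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)[0]
            raise FormatError(
                f"negative intensity at peptide {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_provenance(self, step: str) -> "IntensityMatrix":
        return dataclasses.replace(self, provenance=self.provenance + (step,))


@dataclass(frozen=True)
class SampleMeta:
    """Sample -> (cell line, disease, replicate[, run_order]) map."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        required = {"cell_line", "disease", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups[:5]}")
        bad_disease = sorted(set(df["disease"]) - set(DISEASES))
        if bad_disease:
            raise FormatError(f"unknown disease labels {bad_disease}; allowed: {DISEASES}")
        per_line = df.groupby("cell_line")["disease"].nunique()
        conflicted = per_line[per_line > 1].index.tolist()
        if conflicted:
            raise FormatError(f"cell lines mapped to multiple diseases: {conflicted}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    def cell_line_of(self, sample_id: str) -> str:
        return str(self.data.at[sample_id, "cell_line"])

    def disease_of_line(self, cell_line: str) -> str:
        sub = self.data[self.data["cell_line"] == cell_line]
        if sub.empty:
            raise KeyError(f"unknown cell line {cell_line!r}")
        return str(sub["disease"].iloc[0])

    def samples_of_line(self, cell_line: str) -> list[str]:
        return list(self.data.index[self.data["cell_line"] == cell_line])

    def disease_groups(self) -> dict[str, list[str]]:
        """Disease -> list of sample ids, diseases sorted."""
        out: dict[str, list[str]] = {}
        for disease in sorted(self.data["disease"].unique()):
            out[disease] = list(self.data.index[self.data["disease"] == disease])
        return out


@dataclass(frozen=True)
class ViabilityTable:
    """(cell_line, drug) -> viability as % of DMSO control."""

    data: pd.DataFrame  # columns cell_line, drug, viability_percent

    def __post_init__(self) -> None:
        df = self.data
        required = {"cell_line", "drug", "viability_percent"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"viability table missing columns: {sorted(missing)}")
        if df.duplicated(subset=["cell_line", "drug"]).any():
            dups = df[df.duplicated(subset=["cell_line", "drug"], keep=False)]
            pairs = sorted(set(zip(dups["cell_line"], dups["drug"])))
            raise FormatError(f"duplicate (cell_line, drug) entries: {pairs[:5]}")
        v = df["viability_percent"].to_numpy(dtype=float)
        if len(v) and (not np.all(np.isfinite(v)) or np.any(v <= 0) or np.any(v > 200)):
            raise FormatError("viability_percent values must be finite and in (0, 200]")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def drugs(self) -> list[str]:
        return sorted(self.data["drug"].unique())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    def value(self, cell_line: str, drug: str) -> float:
        sub = self.data[(self.data["cell_line"] == cell_line) & (self.data["drug"] == drug)]
        if sub.empty:
            raise KeyError(f"no viability entry for ({cell_line!r}, {drug!r})")
        return float(sub["viability_percent"].iloc[0])

    def for_drug(self, drug: str) -> pd.Series:
        """Viability per cell line for one drug (Series indexed by cell line)."""
        sub = self.data[self.data["drug"] == drug]
        if sub.empty:
            raise KeyError(f"unknown drug {drug!r}; available: {self.drugs}")
        return sub.set_index("cell_line")["viability_percent"].astype(float)


@dataclass(frozen=True)
class PhosphoSiteAnnotation:
    """Location of a phosphosite within its protein (1-based)."""

    peptide_id: str
    protein_id: str
    position: int
    residue: str
    gene: str = ""
    ambiguous: bool = False
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"site position must be >= 1, got {self.position} for {self.peptide_id!r}"
            )
        if self.residue not in ("S", "T", "Y"):
            raise FormatError(
                f"residue must be one of S/T/Y, got {self.residue!r} for {self.peptide_id!r}"
            )


# ---------------------------------------------------------------------------
# Intensity matrix IO
# ---------------------------------------------------------------------------


def read_intensity_matrix(
    path: str | Path, missing_policy: str = "error"
) -> IntensityMatrix:
    """Read a peptide x sample intensity table.

    missing_policy
        ``"error"`` rejects any missing cell; ``"drop_peptide"`` removes
        peptides with any missing value; ``"impute_half_min"`` replaces each
        missing cell with half the peptide's minimum observed value.
    """
    if missing_policy not in ("error", "drop_peptide", "impute_half_min"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric cell at peptide {bad[0]!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
    if df.isna().any().any():
        if missing_policy == "error":
            r = df.index[df.isna().any(axis=1)][0]
            c = df.columns[df.isna().any(axis=0)][0]
            raise FormatError(
                f"missing value (peptide {r!r}, e.g. sample {c!r}) with missing_policy='error'"
            )
        if missing_policy == "drop_peptide":
            df = df.dropna(axis=0, how="any")
        else:  # impute_half_min
            row_min = df.min(axis=1, skipna=True)
            if row_min.isna().any():
                r = row_min.index[row_min.isna()][0]
                raise FormatError(f"peptide {r!r} has no observed values to impute from")
            fill = df.apply(lambda row: row.fillna(row_min[row.name] / 2.0), axis=1)
            df = fill
    return IntensityMatrix(df)


def write_intensity_matrix(m: IntensityMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FORMAT, index_label="peptide_id")


# ---------------------------------------------------------------------------
# Metadata, viability, sites, FASTA
# ---------------------------------------------------------------------------


def read_sample_meta(path: str | Path) -> SampleMeta:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "cell_line": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"sample metadata {path} must have a 'sample_id' column")
    return SampleMeta(df.set_index("sample_id"))


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_viability(path: str | Path) -> ViabilityTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"cell_line": str, "drug": str})
    return ViabilityTable(df)


def write_viability(v: ViabilityTable, path: str | Path) -> None:
    v.data.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FORMAT, index=False)


def read_site_annotations(path: str | Path) -> list[PhosphoSiteAnnotation]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"peptide_id": str, "protein_id": str})
    required = {"peptide_id", "protein_id", "position", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"site annotation file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        charge = getattr(row, "charge", None)
        if charge is not None and not (isinstance(charge, float) and math.isnan(charge)):
            charge = int(charge)
        else:
            charge = None
        out.append(
            PhosphoSiteAnnotation(
                peptide_id=row.peptide_id,
                protein_id=row.protein_id,
                position=int(row.position),
                residue=str(row.residue),
                gene=str(getattr(row, "gene", "") or ""),
                ambiguous=bool(getattr(row, "ambiguous", False)),
                charge=charge,
            )
        )
    return out


def write_site_annotations(sites: Iterable[PhosphoSiteAnnotation], path: str | Path) -> None:
    rows = [
        {
            "peptide_id": s.peptide_id,
            "protein_id": s.protein_id,
            "gene": s.gene,
            "position": s.position,
            "residue": s.residue,
            "ambiguous": s.ambiguous,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> sequence map."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"duplicate protein id {record.id!r} in {path}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cross-file referential integrity
# ---------------------------------------------------------------------------


def validate_bundle(
    matrix: IntensityMatrix,
    meta: SampleMeta,
    viability: ViabilityTable | None = None,
    sites: Iterable[PhosphoSiteAnnotation] | None = None,
) -> None:
    """Check referential integrity across loaded objects; raise listing offenders."""
    orphan_samples = sorted(set(matrix.sample_ids) - set(meta.sample_ids))
    if orphan_samples:
        raise FormatError(f"matrix samples absent from metadata: {orphan_samples}")
    if viability is not None and len(viability.data):
        lines_in_matrix = {meta.cell_line_of(s) for s in matrix.sample_ids}
        missing = sorted(lines_in_matrix - set(viability.cell_lines))
        if missing:
            raise FormatError(f"cell lines without viability entries: {missing}")
    if sites is not None:
        orphan_peptides = sorted(
            {s.peptide_id for s in sites} - set(matrix.peptide_ids)
        )
        if orphan_peptides:
            raise FormatError(
                f"annotated peptides absent from matrix: {orphan_peptides[:10]}"
            )
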