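"""Readers, writers and the central dataset container.

The pipeline's central table is an intensity matrix: one row per molecular
formula, one column per sample, with sample metadata (lake, treatment,
timepoint, replicate, role) attached. All files are comma-separated UTF-8
text with a header row and "." decimal separator, matching common FT-ICR MS
export practice.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formula import MolecularFormula, format_formula, parse_formula

LAKES = ("alpine", "subarctic")
TREATMENTS = ("control", "s_above", "s_below")
ROLES = ("sample", "blank")

METADATA_COLUMNS = ("sample_id", "lake", "treatment", "timepoint_h", "replicate", "role")


@dataclass(frozen=True)
class SampleSpec:
    """Identity and design position of one measured sample.

    ``(lake, treatment, timepoint_h, replicate)`` uniquely identifies a
    sample within a dataset. Blank samples never enter diversity or
    enrichment computations; they only drive peak filtering.
    """

    sample_id: str
    lake: str
    treatment: str
    timepoint_h: float
    replicate: int
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.lake not in LAKES:
            raise ValueError(f"unknown lake {self.lake!r}; expected one of {LAKES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def group(self) -> tuple[str, str, float]:
        """Replicate-group key: (lake, treatment, timepoint_h)."""
        return (self.lake, self.treatment, self.timepoint_h)


@dataclass
class Dataset:
    """Formulae x samples intensity matrix plus sample metadata.

    ``intensities`` is indexed by serialized formula strings and has one
    column per ``sample_id``. ``provenance`` is an append-only log of the
    operations applied; every transforming stage records itself.
    """

    intensities: pd.DataFrame
    samples: list[SampleSpec]
    normalized: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        keys = [(s.lake, s.treatment, s.timepoint_h, s.replicate, s.role) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (lake, treatment, timepoint, replicate, role) in metadata")
        missing = set(ids) ^ set(self.intensities.columns)
        if missing:
            raise ValueError(f"sample/column mismatch for: {sorted(missing)}")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate formula rows: {dups}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        # keep column order aligned with metadata order
        self.intensities = self.intensities[ids]

    # -- accessors ---------------------------------------------------------

    @property
    def formulae(self) -> list[MolecularFormula]:
        return [parse_formula(s) for s in self.intensities.index]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def spec(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select_samples(self, **criteria) -> list[SampleSpec]:
        """Samples matching equality criteria on SampleSpec fields."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in criteria.items()):
                out.append(s)
        return out

    def replicate_groups(self, role: str = "sample") -> dict[tuple, list[SampleSpec]]:
        """Samples of ``role`` grouped by (lake, treatment, timepoint_h)."""
        groups: dict[tuple, list[SampleSpec]] = {}
        for s in self.samples:
            if s.role == role:
                groups.setdefault(s.group, []).append(s)
        return groups

    # -- transformation helpers -------------------------------------------

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def with_intensities(
        self,
        intensities: pd.DataFrame,
        note: str,
        samples: list[SampleSpec] | None = None,
        normalized: bool | None = None,
    ) -> "Dataset":
        """New Dataset with replaced matrix and an appended provenance note."""
        return Dataset(
            intensities=intensities,
            samples=list(self.samples if samples is None else samples),
            normalized=self.normalized if normalized is None else normalized,
            provenance=[*self.provenance, note],
        )


def read_metadata(path: str | Path) -> list[SampleSpec]:
    """Read a sample-metadata CSV into SampleSpec records."""
    meta = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {path} missing columns: {sorted(missing)}")
    return [
        SampleSpec(
            sample_id=str(r.sample_id),
            lake=str(r.lake),
            treatment=str(r.treatment),
            timepoint_h=float(r.timepoint_h),
            replicate=int(r.replicate),
            role=str(r.role),
        )
        for r in meta.itertuples(index=False)
    ]


def read_peak_table(path: str | Path, metadata_path: str | Path) -> Dataset:
    """Read an assigned peak table plus sample metadata into a Dataset.

    The peak table has one row per formula with columns
    ``formula, neutral_mass`` plus one intensity column per sample_id.
    Missing intensities are read as 0. Duplicate formula rows and any
    mismatch between metadata sample ids and table columns are rejected.
    """
    samples = read_metadata(metadata_path)
    table = pd.read_csv(path)
    if "formula" not in table.columns:
        raise ValueError(f"peak table {path} has no 'formula' column")
    # parse (and normalize serialization of) every formula up front
    formulas = [format_formula(parse_formula(s)) for s in table["formula"].astype(str)]
    dup = pd.Index(formulas)[pd.Index(formulas).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate formula rows in {path}: {dup}")
    ids = [s.sample_id for s in samples]
    table_cols = [c for c in table.columns if c not in ("formula", "neutral_mass")]
    missing_in_table = sorted(set(ids) - set(table_cols))
    missing_in_meta = sorted(set(table_cols) - set(ids))
    if missing_in_table or missing_in_meta:
        raise ValueError(
            f"sample/column mismatch: in metadata but not table {missing_in_table}; "
            f"in table but not metadata {missing_in_meta}"
        )
    intens = table[ids].fillna(0.0).astype(float)
    intens.index = pd.Index(formulas, name="formula")
    d = Dataset(intensities=intens, samples=samples)
    d.log(f"read_peak_table: {len(formulas)} formulae x {len(ids)} samples from {Path(path).name}")
    return d


def write_peak_table(d: Dataset, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write a Dataset back to the canonical peak-table / metadata CSV pair."""
    out = d.intensities.copy()
    out.insert(0, "neutral_mass", [f.mass for f in d.formulae])
    out.to_csv(path, index=True)
    if metadata_path is not None:
        write_metadata(d.samples, metadata_path)


def write_metadata(samples: list[SampleSpec], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples])[list(METADATA_COLUMNS)].to_csv(
        path, index=False
    )


def write_results(
    obj: pd.DataFrame,
    path: str | Path,
    *,
    parameters: dict | None = None,
    seed: int | None = None,
    index: bool = True,
) -> Path:
    """Write a tabular result as CSV plus a machine-readable run summary.

    Floats are written at full round-trip precision, so reading the file back
    reproduces the table exactly. The sidecar ``<path>.meta.json`` records
    the parameters, seed and software version of the run.
    """
    from . import __version__

    path = Path(path)
    obj.to_csv(path, index=index)
    summary = {
        "software": "domchemo",
        "version": __version__,
        "rows": int(obj.shape[0]),
        "columns": list(map(str, obj.columns)),
        "parameters": parameters or {},
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(summary, indent=2))
    return path


def read_results(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, index_col=index_col)
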