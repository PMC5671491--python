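"""Domain types and table I/O for isoprenoid GDGT datasets.

The central container is :class:`Dataset`, an ordered collection of
:class:`SampleRecord` objects.  Each record describes one field sample
(suspended particulate matter or surface sediment): station metadata,
per-lipid-pool GDGT profiles and/or pre-computed proxy indices, and qPCR
16S rRNA gene abundances for total archaea and Marine Group II (MG-II)
Euryarchaeota.

GDGT fractional abundances are stored in **percent** (0-100) of the
isoprenoid GDGT pool, the scale the ring-index formulas presume.  Readers
can accept fraction-scale (0-1) input via ``abundance_scale="fraction"``.

Missing values: the tokens "–" (en dash), "-", "" and "NA" all map to an
*absent* optional field, never to zero — zero is a measurement, absence
is not.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "POOLS",
    "WATER_TYPES",
    "MISSING_TOKENS",
    "GDGTProfile",
    "BrGDGTProfile",
    "SampleRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "normalize_profile",
    "read_gdgt_table",
    "write_results",
    "read_results",
    "load_table1_fixture",
    "profile_table_schema",
    "write_dataset_table",
]

#: Lipid pools distinguished throughout: core lipids, acid-hydrolysis
#: (glycosidic + phosphatidyl) intact polar lipids, and base-hydrolysis
#: (phosphatidyl-only) intact polar lipids.
POOLS = ("CL", "total_IPL", "phospho_IPL")

WATER_TYPES = ("river", "mixing", "sea", "sediment")

MISSING_TOKENS = frozenset({"–", "-", "", "NA"})

#: Allowed deviation of a validated profile's field sum from 100 percent.
DEFAULT_SUM_TOL = 0.5


class SchemaError(ValueError):
    """A required column is missing or a schema entry is malformed."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# profiles


@dataclass(frozen=True)
class GDGTProfile:
    """Fractional abundances (percent) of the seven isoprenoid GDGTs.

    Fields are GDGT-0 through GDGT-4 (``g0`` .. ``g4``, carrying 0-4
    cyclopentane rings), crenarchaeol (``cren``) and the crenarchaeol
    regioisomer (``cren_iso``).
    """

    g0: float
    g1: float
    g2: float
    g3: float
    g4: float
    cren: float
    cren_iso: float

    def total(self) -> float:
        return (
            self.g0 + self.g1 + self.g2 + self.g3 + self.g4
            + self.cren + self.cren_iso
        )

    def as_tuple(self) -> tuple[float, ...]:
        return dataclasses.astuple(self)

    def validate(self, sum_tol: float = DEFAULT_SUM_TOL) -> "GDGTProfile":
        for name in ("g0", "g1", "g2", "g3", "g4", "cren", "cren_iso"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"GDGT abundance {name} must be >= 0, got {v!r}")
        s = self.total()
        if abs(s - 100.0) > sum_tol:
            raise ValidationError(
                f"GDGT abundances sum to {s:g}, outside 100 +/- {sum_tol:g}"
            )
        return self


@dataclass(frozen=True)
class BrGDGTProfile:
    """Abundances of the three major branched GDGTs (percent scale).

    Only needed for the BIT terrestrial-input flag; the branched and
    isoprenoid abundances must be on a common response scale.
    """

    br_Ia: float
    br_IIa: float
    br_IIIa: float

    def total(self) -> float:
        return self.br_Ia + self.br_IIa + self.br_IIIa

    def validate(self) -> "BrGDGTProfile":
        for name in ("br_Ia", "br_IIa", "br_IIIa"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"branched abundance {name} must be >= 0, got {v!r}")
        return self


def normalize_profile(p: GDGTProfile) -> GDGTProfile:
    """Rescale a profile so its fields sum to exactly 100 percent."""
    s = p.total()
    if s <= 0:
        raise ValidationError("cannot normalize an all-zero GDGT profile")
    k = 100.0 / s
    return GDGTProfile(*(v * k for v in p.as_tuple()))


# ---------------------------------------------------------------------------
# records and datasets


@dataclass
class SampleRecord:
    """One field sample with metadata, lipid data and gene abundances.

    ``profiles`` and ``indices`` are keyed by lipid pool (see
    :data:`POOLS`); either may be present per pool.  ``indices`` holds an
    :class:`~gdgtproxy.indices.IndexSet` (or any object exposing the index
    attributes) for datasets, such as published tables, where only derived
    index values are available.  Gene abundances are qPCR copies per liter.
    """

    sample_id: str
    station: str = ""
    water_type: str = "sea"
    depth: float | None = None
    temperature: float | None = None
    salinity: float | None = None
    ph: float | None = None
    iso_conc: dict[str, float] = field(default_factory=dict)
    profiles: dict[str, GDGTProfile] = field(default_factory=dict)
    br_profiles: dict[str, BrGDGTProfile] = field(default_factory=dict)
    indices: dict[str, object] = field(default_factory=dict)
    archaea_16s: float | None = None
    mgii_16s: float | None = None
    extra: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.water_type not in WATER_TYPES:
            raise ValidationError(
                f"{self.sample_id}: water_type {self.water_type!r} not one of {WATER_TYPES}"
            )
        for name in ("depth", "archaea_16s", "mgii_16s"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0, got {v!r}")
        for pool, c in self.iso_conc.items():
            if c < 0:
                raise ValidationError(f"{self.sample_id}: iso_conc[{pool}] must be >= 0")

    @property
    def is_spm(self) -> bool:
        return self.water_type != "sediment"


@dataclass
class Dataset:
    """Ordered, uniquely-identified collection of :class:`SampleRecord`."""

    records: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("Dataset must contain at least one record")
        seen: set[str] = set()
        for r in self.records:
            if r.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, predicate) -> "Dataset":
        kept = [r for r in self.records if predicate(r)]
        return Dataset(kept, provenance=self.provenance)

    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]


# ---------------------------------------------------------------------------
# reading


_PROFILE_FIELDS = ("g0", "g1", "g2", "g3", "g4", "cren", "cren_iso")
_INDEX_FIELDS = ("tex86", "ri1", "ri2", "methane_index", "pct_gdgt2",
                 "ratio_2_3", "ratio_0_cren", "ratio_2_cren", "bit")
_META_FIELDS: Mapping[str, str] = {
    "sample_id": "str",
    "station": "str",
    "water_type": "str",
    "depth": "float",
    "temperature": "float",
    "salinity": "float",
    "ph": "float",
    "archaea_16s": "float",
    "mgii_16s": "float",
}


def _parse_cell(raw) -> float | None:
    """Parse one numeric cell; missing tokens and NaN map to None."""
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    s = str(raw).strip()
    if s in MISSING_TOKENS:
        return None
    return float(s)  # handles scientific notation like 5.7E+08


def read_gdgt_table(path, schema: Mapping, *, sum_tol: float = DEFAULT_SUM_TOL) -> Dataset:
    """Read a delimited sample table into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row (delimiter sniffed from the
        extension; ``.tsv`` means tab).
    schema
        Column-mapping configuration with keys drawn from:

        - metadata fields (``sample_id`` mandatory; ``station``,
          ``water_type``, ``depth``, ``temperature``, ``salinity``, ``ph``,
          ``archaea_16s``, ``mgii_16s`` optional) mapping to column names;
        - ``profiles``: ``{pool: {g0: col, ..., cren_iso: col}}``;
        - ``indices``: ``{pool: {tex86: col, ri2: col, ...}}``;
        - ``iso_conc``: ``{pool: col}``;
        - ``abundance_scale``: ``"percent"`` (default) or ``"fraction"``
          (values multiplied by 100 on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if "sample_id" not in schema:
        raise SchemaError("schema must map 'sample_id'")
    scale = 100.0 if schema.get("abundance_scale", "percent") == "fraction" else 1.0

    def col(name: str) -> str:
        if name not in df.columns:
            raise SchemaError(f"mapped column {name!r} not in table header")
        return name

    for key, colname in schema.items():
        if key in _META_FIELDS:
            col(colname)

    # late import: indices module depends on profile types defined above
    from .indices import IndexSet

    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        def cell(colname: str):
            return row[col(colname)]

        kwargs: dict = {}
        for fieldname, kind in _META_FIELDS.items():
            if fieldname not in schema:
                continue
            raw = cell(schema[fieldname])
            if kind == "str":
                s = str(raw).strip()
                kwargs[fieldname] = s if s not in MISSING_TOKENS else ""
            else:
                kwargs[fieldname] = _parse_cell(raw)
        if not kwargs.get("sample_id"):
            raise ValidationError(f"row {i}: empty sample_id")
        if "water_type" not in kwargs or not kwargs["water_type"]:
            kwargs["water_type"] = "sea"

        profiles: dict[str, GDGTProfile] = {}
        for pool, mapping in schema.get("profiles", {}).items():
            missing = [f for f in _PROFILE_FIELDS if f not in mapping]
            if missing:
                raise SchemaError(f"profiles[{pool}] lacks fields {missing}")
            vals = {f: _parse_cell(cell(mapping[f])) for f in _PROFILE_FIELDS}
            if all(v is None for v in vals.values()):
                continue
            if any(v is None for v in vals.values()):
                raise ValidationError(
                    f"{kwargs['sample_id']}: incomplete {pool} profile"
                )
            prof = GDGTProfile(**{f: v * scale for f, v in vals.items()})
            try:
                profiles[pool] = prof.validate(sum_tol=sum_tol)
            except ValidationError as e:
                raise ValidationError(f"{kwargs['sample_id']} [{pool}]: {e}") from None

        indices: dict[str, IndexSet] = {}
        for pool, mapping in schema.get("indices", {}).items():
            vals = {}
            for f, colname in mapping.items():
                if f not in _INDEX_FIELDS:
                    raise SchemaError(f"unknown index field {f!r}")
                v = _parse_cell(cell(colname))
                vals[f] = math.nan if v is None else v
            if all(math.isnan(v) for v in vals.values()):
                continue
            indices[pool] = IndexSet(**vals)

        iso_conc: dict[str, float] = {}
        for pool, colname in schema.get("iso_conc", {}).items():
            v = _parse_cell(cell(colname))
            if v is not None:
                iso_conc[pool] = v

        extra: dict[str, object] = {}
        for colname in schema.get("extra", ()):
            if colname in df.columns:  # extra columns are optional
                v = _parse_cell(row[colname])
                if v is not None:
                    extra[colname] = v

        records.append(
            SampleRecord(
                profiles=profiles, indices=indices, iso_conc=iso_conc,
                extra=extra, **kwargs,
            )
        )
    return Dataset(records, provenance=str(path))


# ---------------------------------------------------------------------------
# writing results


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return format(v, ".9g")
    return str(v)


def write_results(ds: Dataset, results: Mapping, path) -> None:
    """Write per-(sample, pool) index/screen results as a flat TSV.

    ``results`` maps ``(sample_id, pool)`` to a mapping of column name to
    value (typically the merged fields of an IndexSet and a ScreenResult).
    Numeric values are written with 9 significant digits so the table
    round-trips losslessly at 6 significant digits; missing/undefined
    values become empty cells.
    """
    known = set(ds.ids())
    for sid, _pool in results:
        if sid not in known:
            raise ValidationError(f"results reference unknown sample_id {sid!r}")
    columns: list[str] = []
    for payload in results.values():
        for k in payload:
            if k not in columns:
                columns.append(k)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["sample_id", "pool", *columns]) + "\n")
        for (sid, pool), payload in results.items():
            cells = [sid, pool] + [_fmt(payload.get(c)) for c in columns]
            fh.write("\t".join(cells) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# dataset tables (profile-level round-tripping, used by the simulator/CLI)


def profile_table_schema(pools: Iterable[str] = POOLS) -> dict:
    """Column-mapping schema for tables written by :func:`write_dataset_table`.

    Profile columns follow the ``{pool}_{field}`` convention
    (e.g. ``CL_g0``); metadata columns use their field names.
    """
    return {
        "sample_id": "sample_id",
        "station": "station",
        "water_type": "water_type",
        "depth": "depth",
        "temperature": "temperature",
        "salinity": "salinity",
        "archaea_16s": "archaea_16s",
        "mgii_16s": "mgii_16s",
        "profiles": {
            pool: {f: f"{pool}_{f}" for f in _PROFILE_FIELDS} for pool in pools
        },
        "extra": ("f",),
    }


def write_dataset_table(ds: Dataset, path, pools: Iterable[str] = POOLS) -> None:
    """Write records with profile-level data as a flat CSV.

    The table is readable back through :func:`read_gdgt_table` with
    :func:`profile_table_schema`.  Values are written with 12 significant
    digits, so a write is byte-deterministic for a given dataset.
    """
    pools = list(pools)
    cols = ["sample_id", "station", "water_type", "depth", "temperature",
            "salinity", "archaea_16s", "mgii_16s"]
    prof_cols = [f"{pool}_{f}" for pool in pools for f in _PROFILE_FIELDS]
    extra_keys: list[str] = []
    for r in ds:
        for k in r.extra:
            if k not in extra_keys:
                extra_keys.append(k)

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return "" if math.isnan(v) else format(v, ".12g")
        return str(v)

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(cols + prof_cols + extra_keys) + "\n")
        for r in ds:
            row = [fmt(getattr(r, c)) for c in cols]
            for pool in pools:
                prof = r.profiles.get(pool)
                row += (
                    [fmt(v) for v in prof.as_tuple()] if prof is not None
                    else [""] * len(_PROFILE_FIELDS)
                )
            row += [fmt(r.extra.get(k)) for k in extra_keys]
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# packaged fixture


def _fixture_path() -> Path:
    return Path(importlib.resources.files("gdgtproxy").joinpath("data/table1.csv"))


#: Schema for the packaged transect table (26 samples, Pearl River estuary
#: and coastal South China Sea: 18 SPM + 8 surface sediments).
TABLE1_SCHEMA: dict = {
    "sample_id": "sample_id",
    "station": "station",
    "water_type": "water_type",
    "depth": "depth_m",
    "temperature": "temperature_c",
    "salinity": "salinity",
    "ph": "ph",
    "archaea_16s": "archaea_16s_copies_l",
    "mgii_16s": "mgii_16s_copies_l",
    "iso_conc": {
        "CL": "iso_conc_cl_ng_l",
        "total_IPL": "iso_conc_total_ipl_ng_l",
        "phospho_IPL": "iso_conc_phospho_ipl_ng_l",
    },
    "indices": {
        "CL": {"tex86": "tex86_cl", "ri2": "ri2_cl"},
        "total_IPL": {"tex86": "tex86_total_ipl", "ri2": "ri2_total_ipl"},
        "phospho_IPL": {"tex86": "tex86_phospho_ipl", "ri2": "ri2_phospho_ipl"},
    },
}


def load_table1_fixture() -> Dataset:
    """Load the packaged estuarine-transect table.

    Returns the 26-sample dataset (8 river SPM, 6 mixing SPM, 4 sea SPM,
    8 surface sediments) with per-pool TEX86 and RI_2 values, isoprenoid
    GDGT concentrations, environmental metadata, and archaeal / MG-II 16S
    qPCR abundances for the 12 SPM samples of stations R1, M and S.
    Raw fractional abundances are not part of this table, so profile-level
    recomputation of the indices is not possible from the fixture alone.
    """
    ds = read_gdgt_table(_fixture_path(), TABLE1_SCHEMA)
    ds.provenance = "packaged estuarine transect table (table1.csv)"
    return ds
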