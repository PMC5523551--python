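"""I/O and validation for OTU count tables, library metadata, and pipeline configuration.

The on-disk interchange shape is the de-facto OTU-table layout: a tab-delimited
counts matrix (rows = phylotypes, header row = library ids, first column =
phylotype ids) plus a separate tab-delimited metadata table keyed on
``library_id``. Metadata lives in its own file because the experimental design
(marker gene x treatment x isotope x gradient pool) is too rich to mangle into
column names. BIOM v1 (JSON) count matrices are accepted on read.

All relative abundances in this package are percentages on the 0-100 scale,
matching the thresholds the label classifier uses (0.5%, 0.1%, 5%). Files are
UTF-8 with "." as the decimal separator, independent of locale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "LibraryMetadata",
    "OtuTable",
    "PipelineConfig",
    "read_otu_table",
    "write_otu_table",
    "load_config",
    "MARKERS",
    "EXPERIMENTS",
    "TREATMENTS",
    "ISOTOPES",
    "PH_CONDITIONS",
    "POOLS",
]

MARKERS = ("16S", "mxaF", "ITS")
EXPERIMENTS = ("substrate_sip", "ph_sip")
TREATMENTS = (
    "methanol",
    "acetate",
    "glucose",
    "xylose",
    "vanillic_acid",
    "co2",
    "unsupplemented",
)
ISOTOPES = ("c12", "c13")
PH_CONDITIONS = ("in_situ_4", "elevated_7", "not_applicable")
POOLS = ("H", "M", "L", "unpooled")

#: Plausible range for a CsCl gradient fraction density, g ml^-1.
BD_RANGE = (1.60, 1.80)

_METADATA_COLUMNS = (
    "library_id",
    "marker",
    "experiment",
    "treatment",
    "isotope",
    "ph_condition",
    "pool",
    "buoyant_density",
)


class ValidationError(ValueError):
    """A table, metadata record, or configuration violates an invariant."""


@dataclass(frozen=True)
class LibraryMetadata:
    """Descriptor for one amplicon read library.

    ``buoyant_density`` is required when ``pool == "unpooled"`` (a raw gradient
    fraction) and optional for pooled H/M/L libraries. Unknown metadata columns
    read from disk are preserved verbatim in ``extra``.
    """

    library_id: str
    marker: str
    experiment: str
    treatment: str
    isotope: str
    pool: str
    ph_condition: str = "not_applicable"
    buoyant_density: float | None = None
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.library_id:
            raise ValidationError("library_id must be non-empty")
        _check_enum("marker", self.marker, MARKERS)
        _check_enum("experiment", self.experiment, EXPERIMENTS)
        _check_enum("treatment", self.treatment, TREATMENTS)
        _check_enum("isotope", self.isotope, ISOTOPES)
        _check_enum("ph_condition", self.ph_condition, PH_CONDITIONS)
        _check_enum("pool", self.pool, POOLS)
        bd = self.buoyant_density
        if self.pool == "unpooled" and bd is None:
            raise ValidationError(
                f"library {self.library_id!r}: buoyant_density is required for "
                "unpooled (fraction-level) libraries"
            )
        if bd is not None:
            if not math.isfinite(bd):
                raise ValidationError(
                    f"library {self.library_id!r}: buoyant_density must be finite"
                )
            if not (BD_RANGE[0] <= bd <= BD_RANGE[1]):
                raise ValidationError(
                    f"library {self.library_id!r}: buoyant_density {bd} outside "
                    f"plausible range [{BD_RANGE[0]}, {BD_RANGE[1]}] g/ml"
                )

    @property
    def design_key(self) -> tuple[str, str, str, str, str, str]:
        """The experimental-design coordinates that identify a pooled library."""
        return (
            self.marker,
            self.experiment,
            self.treatment,
            self.isotope,
            self.ph_condition,
            self.pool,
        )


def _check_enum(name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise ValidationError(f"{name} must be one of {allowed}, got {value!r}")


@dataclass
class OtuTable:
    """Integer read counts indexed by (phylotype, library) plus library metadata.

    ``counts`` is a pandas DataFrame with phylotype ids as the index and
    library ids as the columns; ``libraries`` holds one :class:`LibraryMetadata`
    per column. The two are validated for mutual consistency on construction.
    """

    counts: pd.DataFrame
    libraries: list[LibraryMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate phylotype_id(s): {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate library_id(s) in counts: {dups}")
        meta_ids = [m.library_id for m in self.libraries]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValidationError("duplicate library_id in metadata")
        missing = [c for c in counts.columns if c not in set(meta_ids)]
        if missing:
            raise ValidationError(
                f"libraries present in counts but absent from metadata: {missing}"
            )
        orphan = [m for m in meta_ids if m not in set(counts.columns)]
        if orphan:
            raise ValidationError(
                f"libraries present in metadata but absent from counts: {orphan}"
            )
        for col in counts.columns:
            series = counts[col]
            if not pd.api.types.is_integer_dtype(series):
                raise ValidationError(
                    f"counts for library {col!r} are not integers"
                )
            if (series < 0).any():
                bad = series.index[series < 0][0]
                raise ValidationError(
                    f"negative count at phylotype {bad!r}, library {col!r}"
                )
        pooled_keys = [m.design_key for m in self.libraries if m.pool != "unpooled"]
        if len(set(pooled_keys)) != len(pooled_keys):
            seen: set[tuple] = set()
            for key in pooled_keys:
                if key in seen:
                    raise ValidationError(
                        "more than one pooled library for design coordinates "
                        f"(marker, experiment, treatment, isotope, ph, pool) = {key}"
                    )
                seen.add(key)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_phylotypes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def library(self, library_id: str) -> LibraryMetadata:
        for m in self.libraries:
            if m.library_id == library_id:
                return m
        raise KeyError(library_id)

    def subset_libraries(self, library_ids: Sequence[str]) -> "OtuTable":
        ids = list(library_ids)
        return OtuTable(
            counts=self.counts[ids].copy(),
            libraries=[m for m in self.libraries if m.library_id in set(ids)],
        )

    def metadata_frame(self) -> pd.DataFrame:
        extra_keys = sorted({k for m in self.libraries for k, _ in m.extra})
        rows = []
        for m in self.libraries:
            row = {
                "library_id": m.library_id,
                "marker": m.marker,
                "experiment": m.experiment,
                "treatment": m.treatment,
                "isotope": m.isotope,
                "ph_condition": m.ph_condition,
                "pool": m.pool,
                "buoyant_density": m.buoyant_density,
            }
            extras = dict(m.extra)
            for k in extra_keys:
                row[k] = extras.get(k, "")
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_METADATA_COLUMNS) + extra_keys)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the inference procedure, with defaults.

    bd_heavy_min / bd_light_max
        Buoyant-density boundaries of the heavy and light pools, g ml^-1.
        Heavy is inclusive at 1.730, light inclusive at 1.715, middle open on
        both sides.
    min_ra_pct
        Criterion 3: minimum relative abundance (%) in the 13C H or M library.
    min_diff_pct
        Criterion 4: minimum 13C-minus-12C abundance difference, percentage
        points, in the compared fraction class.
    lp_major_pct
        Labeling-proportion threshold (%) separating major from minor labeled
        taxa; inclusive (LP = 5.0 is major).
    its_min_reads / its_rarefy_depth
        ITS route: drop phylotypes with fewer than 3 reads total, then rarefy
        every library to exactly 1503 counts.
    seed
        Master seed for every stochastic stage (rarefaction, simulation).
    """

    bd_heavy_min: float = 1.730
    bd_light_max: float = 1.715
    min_ra_pct: float = 0.5
    min_diff_pct: float = 0.1
    lp_major_pct: float = 5.0
    its_min_reads: int = 3
    its_rarefy_depth: int = 1503
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bd_light_max < self.bd_heavy_min:
            raise ValidationError(
                f"bd_light_max ({self.bd_light_max}) must be < bd_heavy_min "
                f"({self.bd_heavy_min})"
            )
        for name in ("min_ra_pct", "min_diff_pct", "lp_major_pct"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValidationError(f"{name} must be a positive finite number")
        for name in ("its_min_reads", "its_rarefy_depth"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ValidationError(f"{name} must be a positive integer")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file.

    Absent keys take the documented defaults; unknown keys are rejected so
    typos do not silently fall back to defaults. ``path=None`` returns the
    default configuration (optionally with keyword overrides).
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {unknown}")
    for name in ("its_min_reads", "its_rarefy_depth", "seed"):
        if name in data and not isinstance(data[name], bool) and isinstance(
            data[name], float
        ):
            if data[name] != int(data[name]):
                raise ValidationError(f"{name} must be an integer")
            data[name] = int(data[name])
    return PipelineConfig(**data)


# -- reading -------------------------------------------------------------------


def read_otu_table(
    counts_path: str | Path, metadata_path: str | Path
) -> OtuTable:
    """Read a counts matrix (TSV or BIOM v1 JSON) and its metadata TSV.

    Errors are hard and name the offending cell or library: a library present
    in the counts but missing from the metadata, a non-integer count cell, or
    a duplicated phylotype id all abort the read.
    """
    counts_path = Path(counts_path)
    counts = (
        _read_biom_v1(counts_path)
        if _looks_like_biom(counts_path)
        else _read_counts_tsv(counts_path)
    )
    libraries = _read_metadata(metadata_path)
    meta_ids = {m.library_id for m in libraries}
    for lib in counts.columns:
        if lib not in meta_ids:
            raise ValidationError(
                f"library {lib!r} appears in {counts_path} but not in the metadata"
            )
    libraries = [m for m in libraries if m.library_id in set(counts.columns)]
    return OtuTable(counts=counts, libraries=libraries)


def _looks_like_biom(path: Path) -> bool:
    if path.suffix.lower() == ".biom":
        return True
    with open(path, "rb") as fh:
        head = fh.read(64).lstrip()
    return head.startswith(b"{")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    out = {}
    for col in raw.columns:
        values = []
        for pid, cell in raw[col].items():
            values.append(_parse_count(cell, pid, col))
        out[col] = pd.Series(values, index=raw.index, dtype="int64")
    frame = pd.DataFrame(out, index=raw.index)
    frame.index.name = "phylotype_id"
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate phylotype_id(s) in {path}: {dups}")
    return frame


def _parse_count(cell: str, phylotype: str, library: str) -> int:
    text = cell.strip()
    where = f"phylotype {phylotype!r}, library {library!r}"
    if text == "":
        raise ValidationError(f"empty count cell at {where}")
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"non-numeric count {cell!r} at {where}") from None
    if not math.isfinite(value) or value != int(value):
        raise ValidationError(f"non-integer count {cell!r} at {where}")
    if value < 0:
        raise ValidationError(f"negative count {cell!r} at {where}")
    return int(value)


def _read_biom_v1(path: Path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) reader for dense and sparse matrices."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    rows = [str(r["id"]) for r in doc["rows"]]
    cols = [str(c["id"]) for c in doc["columns"]]
    frame = pd.DataFrame(0, index=rows, columns=cols, dtype="int64")
    matrix_type = doc.get("matrix_type", "sparse")
    if matrix_type == "dense":
        for i, row in enumerate(doc["data"]):
            for j, value in enumerate(row):
                frame.iloc[i, j] = _parse_count(str(value), rows[i], cols[j])
    elif matrix_type == "sparse":
        for i, j, value in doc["data"]:
            frame.iloc[int(i), int(j)] = _parse_count(
                str(value), rows[int(i)], cols[int(j)]
            )
    else:
        raise ValidationError(f"unsupported BIOM matrix_type {matrix_type!r}")
    frame.index.name = "phylotype_id"
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate phylotype_id(s) in {path}: {dups}")
    return frame


def _read_metadata(path: str | Path) -> list[LibraryMetadata]:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in _METADATA_COLUMNS if c != "buoyant_density"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"metadata file {path} lacks column(s): {missing}")
    extra_cols = [c for c in raw.columns if c not in _METADATA_COLUMNS]
    libraries = []
    for _, row in raw.iterrows():
        bd_text = str(row.get("buoyant_density", "")).strip()
        bd = float(bd_text) if bd_text else None
        libraries.append(
            LibraryMetadata(
                library_id=str(row["library_id"]),
                marker=str(row["marker"]),
                experiment=str(row["experiment"]),
                treatment=str(row["treatment"]),
                isotope=str(row["isotope"]),
                ph_condition=str(row["ph_condition"]),
                pool=str(row["pool"]),
                buoyant_density=bd,
                extra=tuple((c, str(row[c])) for c in extra_cols),
            )
        )
    return libraries


# -- writing -------------------------------------------------------------------


def write_otu_table(
    table: OtuTable, counts_path: str | Path, metadata_path: str | Path
) -> None:
    """Write counts and metadata as TSV; inverse of :func:`read_otu_table`.

    Round-trip exactness is part of the contract: counts are bit-identical and
    every metadata field (including preserved unknown columns) survives.
    """
    counts = table.counts.copy()
    counts.index.name = "phylotype_id"
    counts.to_csv(counts_path, sep="\t", encoding="utf-8")
    meta = table.metadata_frame()
    meta["buoyant_density"] = meta["buoyant_density"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
    )
    meta.to_csv(metadata_path, sep="\t", index=False, encoding="utf-8")
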