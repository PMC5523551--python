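"""Classify gradient fractions into H/M/L density pools and pool their counts.

After isopycnic CsCl centrifugation a gradient is collected as 10 fractions of
measured buoyant density (BD). Fractions are pooled into 'heavy' (H,
BD >= 1.730 g/ml), 'middle' (M, 1.715 < BD < 1.730) and 'light'
(L, BD <= 1.715) libraries; the boundary inclusivities follow the printed
inequalities exactly. Pooling sums read counts where the wet-lab protocol
pooled DNA, and replicate gradients of the same treatment are summed
count-wise before relative abundances are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .tables_io import (
    LibraryMetadata,
    OtuTable,
    PipelineConfig,
    ValidationError,
)

__all__ = [
    "POOL_ORDER",
    "FractionRecord",
    "PooledLibrary",
    "assign_pool",
    "pool_fractions",
    "pool_replicate_gradients",
    "relative_abundance",
    "pooled_to_otu_table",
    "read_fraction_table",
    "write_fraction_table",
]

#: Density pools from light to heavy; assign_pool is monotone along this order.
POOL_ORDER = ("L", "M", "H")


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction: its measured density and its read counts."""

    gradient_id: str
    fraction_index: int
    buoyant_density: float
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not (1 <= self.fraction_index <= 10):
            raise ValidationError(
                f"fraction_index must be 1-10, got {self.fraction_index}"
            )
        if not math.isfinite(self.buoyant_density):
            raise ValidationError("buoyant_density must be finite")
        for pid, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValidationError(
                    f"fraction {self.gradient_id}/{self.fraction_index}: "
                    f"invalid count {n!r} for {pid!r}"
                )


@dataclass
class PooledLibrary:
    """Counts (and optionally relative abundances, %) for one pooled library."""

    metadata: LibraryMetadata
    counts: pd.Series
    relative_abundance: pd.Series | None = None

    @property
    def pool(self) -> str:
        return self.metadata.pool

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


def assign_pool(bd: float, config: PipelineConfig | None = None) -> str:
    """Map a buoyant density (g/ml) to its pool: H, M, or L.

    H iff bd >= bd_heavy_min (default 1.730); L iff bd <= bd_light_max
    (default 1.715); M on the open interval between.
    """
    config = config or PipelineConfig()
    if not math.isfinite(bd):
        raise ValidationError(f"buoyant density must be finite, got {bd!r}")
    if bd >= config.bd_heavy_min:
        return "H"
    if bd <= config.bd_light_max:
        return "L"
    return "M"


def pool_fractions(
    fractions: Iterable[FractionRecord],
    meta: LibraryMetadata,
    config: PipelineConfig | None = None,
) -> list[PooledLibrary]:
    """Sum fraction counts into one library per density pool present.

    All fractions must belong to the same gradient; phylotype universes are
    unioned with absent counts treated as zero. Pools with no member fraction
    are absent from the output, which is ordered heavy to light.
    """
    config = config or PipelineConfig()
    fractions = list(fractions)
    if not fractions:
        raise ValidationError("cannot pool an empty list of fractions")
    gradient_ids = {f.gradient_id for f in fractions}
    if len(gradient_ids) > 1:
        raise ValidationError(
            f"fractions span multiple gradients {sorted(gradient_ids)}; "
            "pool each gradient separately (see pool_replicate_gradients)"
        )
    phylotypes = sorted({pid for f in fractions for pid in f.counts})
    sums: dict[str, pd.Series] = {}
    for frac in fractions:
        pool = assign_pool(frac.buoyant_density, config)
        vec = pd.Series(
            [int(frac.counts.get(pid, 0)) for pid in phylotypes],
            index=phylotypes,
            dtype="int64",
        )
        sums[pool] = sums[pool].add(vec, fill_value=0).astype("int64") if pool in sums else vec
    out = []
    for pool in reversed(POOL_ORDER):  # H, M, L
        if pool in sums:
            pool_meta = replace(
                meta,
                library_id=f"{meta.library_id}_{pool}",
                pool=pool,
                buoyant_density=None,
            )
            out.append(PooledLibrary(metadata=pool_meta, counts=sums[pool]))
    return out


def pool_replicate_gradients(
    fractions: Iterable[FractionRecord],
    meta: LibraryMetadata,
    config: PipelineConfig | None = None,
) -> list[PooledLibrary]:
    """Pool fractions from replicate gradients of one treatment, summing counts.

    Each gradient is pooled on its own measured densities, then per-pool counts
    are summed across gradients — the in-silico analogue of pooling replicate
    DNA before sequencing.
    """
    by_gradient: dict[str, list[FractionRecord]] = {}
    for frac in fractions:
        by_gradient.setdefault(frac.gradient_id, []).append(frac)
    if not by_gradient:
        raise ValidationError("cannot pool an empty list of fractions")
    merged: dict[str, pd.Series] = {}
    for gradient_id in sorted(by_gradient):
        for lib in pool_fractions(by_gradient[gradient_id], meta, config):
            pool = lib.pool
            merged[pool] = (
                merged[pool].add(lib.counts, fill_value=0).astype("int64")
                if pool in merged
                else lib.counts
            )
    out = []
    for pool in reversed(POOL_ORDER):
        if pool in merged:
            pool_meta = replace(
                meta,
                library_id=f"{meta.library_id}_{pool}",
                pool=pool,
                buoyant_density=None,
            )
            out.append(
                PooledLibrary(metadata=pool_meta, counts=merged[pool].sort_index())
            )
    return out


def relative_abundance(lib: PooledLibrary) -> PooledLibrary:
    """Fill per-phylotype relative abundances (%, summing to 100)."""
    total = lib.total_reads
    if total <= 0:
        raise ValidationError(
            f"empty library {lib.metadata.library_id!r}: cannot compute "
            "relative abundances"
        )
    ra = 100.0 * lib.counts.astype(float) / float(total)
    return PooledLibrary(metadata=lib.metadata, counts=lib.counts, relative_abundance=ra)


def pooled_to_otu_table(pooled: Iterable[PooledLibrary]) -> OtuTable:
    """Assemble pooled libraries into one :class:`OtuTable` (union of phylotypes)."""
    pooled = list(pooled)
    if not pooled:
        raise ValidationError("no pooled libraries to assemble")
    phylotypes = sorted({pid for lib in pooled for pid in lib.counts.index})
    counts = pd.DataFrame(index=pd.Index(phylotypes, name="phylotype_id"))
    for lib in pooled:
        counts[lib.metadata.library_id] = (
            lib.counts.reindex(phylotypes).fillna(0).astype("int64")
        )
    return OtuTable(counts=counts, libraries=[lib.metadata for lib in pooled])


# -- fraction-level TSV --------------------------------------------------------


def read_fraction_table(path: str | Path) -> list[FractionRecord]:
    """Read a fraction-level TSV: gradient_id, fraction_index, buoyant_density,
    then one column per phylotype."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ("gradient_id", "fraction_index", "buoyant_density")
    missing = [c for c in fixed if c not in raw.columns]
    if missing:
        raise ValidationError(f"fraction table {path} lacks column(s): {missing}")
    phylotypes = [c for c in raw.columns if c not in fixed]
    records = []
    for _, row in raw.iterrows():
        counts = {}
        for pid in phylotypes:
            text = str(row[pid]).strip()
            value = float(text) if text else 0.0
            if not math.isfinite(value) or value != int(value) or value < 0:
                raise ValidationError(
                    f"invalid count {row[pid]!r} for {pid!r} in {path}"
                )
            counts[pid] = int(value)
        records.append(
            FractionRecord(
                gradient_id=str(row["gradient_id"]),
                fraction_index=int(float(row["fraction_index"])),
                buoyant_density=float(row["buoyant_density"]),
                counts=counts,
            )
        )
    return records


def write_fraction_table(
    fractions: Iterable[FractionRecord], path: str | Path
) -> None:
    fractions = list(fractions)
    phylotypes = sorted({pid for f in fractions for pid in f.counts})
    rows = []
    for f in fractions:
        row = {
            "gradient_id": f.gradient_id,
            "fraction_index": f.fraction_index,
            "buoyant_density": repr(float(f.buoyant_density)),
        }
        for pid in phylotypes:
            row[pid] = int(f.counts.get(pid, 0))
        rows.append(row)
    frame = pd.DataFrame(
        rows, columns=["gradient_id", "fraction_index", "buoyant_density"] + phylotypes
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
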