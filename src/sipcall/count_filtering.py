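"""Read-count filters applied before relative abundances are computed.

Three filters, routed by marker gene:

* 16S and mxaF: phylotypes that occur exactly once across the complete set of
  libraries are treated as sequencing artifacts and removed; singletons within
  an individual library are preserved as long as the dataset-wide total is
  at least 2 (``remove_dataset_singletons``).
* ITS: phylotypes with fewer than 3 reads in total are removed
  (``apply_min_count``), then every library is rarefied — uniform subsampling
  without replacement — to exactly 1503 counts (``rarefy``); libraries too
  shallow for the target depth are dropped with a logged warning.

All-zero phylotype rows are dropped by every filter, and every filter is
idempotent.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

from .tables_io import OtuTable, PipelineConfig, ValidationError

__all__ = [
    "remove_dataset_singletons",
    "apply_min_count",
    "rarefy",
    "filter_for_marker",
]

logger = logging.getLogger(__name__)


def remove_dataset_singletons(table: OtuTable) -> OtuTable:
    """Drop phylotypes whose grand-total count across all libraries is < 2.

    A phylotype counted once in each of two libraries (total 2) is retained:
    only dataset-wide singletons are considered erroneous. All-zero rows carry
    no information and are dropped too.
    """
    totals = table.counts.sum(axis=1)
    keep = totals >= 2
    return OtuTable(
        counts=table.counts.loc[keep].copy(), libraries=list(table.libraries)
    )


def apply_min_count(table: OtuTable, min_reads: int) -> OtuTable:
    """Drop phylotypes with grand-total count below ``min_reads``."""
    if min_reads < 1:
        raise ValidationError(f"min_reads must be >= 1, got {min_reads}")
    totals = table.counts.sum(axis=1)
    keep = (totals >= min_reads) & (totals > 0)
    return OtuTable(
        counts=table.counts.loc[keep].copy(), libraries=list(table.libraries)
    )


def _library_rng(seed: int, library_id: str) -> np.random.Generator:
    # Sub-stream per library derived from the library id, so rarefaction is
    # reproducible independent of library order in the table.
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(library_id.encode("utf-8"))])
    )


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every library, without replacement, to exactly ``depth`` reads.

    Libraries with fewer than ``depth`` total reads are dropped with a logged
    warning. A library at exactly ``depth`` is returned unchanged. Output is
    deterministic for a given seed; each library draws from its own seed
    sub-stream keyed on its id.
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    kept_cols: list[str] = []
    new_cols: dict[str, pd.Series] = {}
    for lib in table.counts.columns:
        column = table.counts[lib]
        total = int(column.sum())
        if total < depth:
            logger.warning(
                "dropping library %r: %d reads < rarefaction depth %d",
                lib, total, depth,
            )
            continue
        kept_cols.append(lib)
        if total == depth:
            new_cols[lib] = column.astype("int64")
            continue
        rng = _library_rng(seed, lib)
        sub = rng.multivariate_hypergeometric(
            column.to_numpy(dtype="int64"), depth
        )
        new_cols[lib] = pd.Series(sub, index=column.index, dtype="int64")
    counts = pd.DataFrame(new_cols, index=table.counts.index, columns=kept_cols)
    if counts.empty:
        counts = counts.astype("int64")
    keep_rows = counts.sum(axis=1) > 0
    counts = counts.loc[keep_rows]
    libraries = [m for m in table.libraries if m.library_id in set(kept_cols)]
    return OtuTable(counts=counts, libraries=libraries)


def filter_for_marker(
    table: OtuTable, config: PipelineConfig | None = None
) -> OtuTable:
    """Apply the marker-appropriate filter route to a single-marker table.

    16S and mxaF tables get dataset-wide singleton removal; ITS tables get the
    minimum-read filter followed by rarefaction to the configured depth.
    """
    config = config or PipelineConfig()
    markers = {m.marker for m in table.libraries}
    if len(markers) != 1:
        raise ValidationError(
            f"filter routing needs a single-marker table, found markers {sorted(markers)}"
        )
    (marker,) = markers
    if marker in ("16S", "mxaF"):
        return remove_dataset_singletons(table)
    filtered = apply_min_count(table, config.its_min_reads)
    return rarefy(filtered, config.its_rarefy_depth, seed=config.seed)
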