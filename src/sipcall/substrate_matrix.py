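"""Cross-treatment substrate-range synthesis of label calls.

Phylotypes labeled (or weakly labeled) in an anchor treatment — typically
the methanol treatment of a methylotrophy experiment — form the rows; every
(treatment,
fraction class) comparison forms a column. Cells carry a three-way state:
``major`` (potentially labeled with LP >= 5%), ``minor`` (labeled with a
smaller LP), or ``unlabeled``. Congruent labeling of a phylotype in the anchor
and in an alternative-substrate treatment estimates its putative substrate
range; phylotypes labeled only in non-anchor treatments are excluded from the
rows. Rows are additionally annotated for possible cross-feeding via 13CO2
assimilation: a row phylotype that is labeled or weakly labeled in any CO2
treatment is a potential cross-feeder, otherwise cross-feeding is considered
negligible (not assessable when the dataset has no CO2 treatment).

Cells encode states, not colors; rendering (black / gray / white in the
field's customary figure style) is a presentation concern behind the optional
plotting helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .label_caller import LabelCall, TreatmentCalls, TreatmentKey
from .tables_io import PipelineConfig, ValidationError

__all__ = [
    "SubstrateRangeMatrix",
    "build_matrix",
    "flag_co2_crossfeeding",
    "plot_matrix",
]

#: Cell states, weakest to strongest.
CELL_STATES = ("unlabeled", "minor", "major")


@dataclass
class SubstrateRangeMatrix:
    """Phylotypes (anchored on one treatment) x (treatment, fraction) states.

    ``cells`` has phylotype ids as the index and a two-level column index
    (treatment label, fraction class); ``anchor_fraction`` records whether a
    row phylotype entered via the anchor's H or M fraction; ``annotations``
    (after :func:`flag_co2_crossfeeding`) holds the per-row CO2 cross-feeding
    flag.
    """

    anchor: TreatmentKey
    cells: pd.DataFrame
    anchor_fraction: pd.Series
    annotations: pd.Series | None = None

    @property
    def phylotypes(self) -> list[str]:
        return list(self.cells.index)

    def merged(self) -> pd.DataFrame:
        """One column per treatment, keeping the strongest of the H/M states."""
        rank = {state: i for i, state in enumerate(CELL_STATES)}
        treatments = list(dict.fromkeys(self.cells.columns.get_level_values(0)))
        out = pd.DataFrame(index=self.cells.index, columns=treatments, dtype=object)
        for treatment in treatments:
            sub = self.cells[treatment]
            out[treatment] = sub.apply(
                lambda row: max(row, key=lambda s: rank[s]), axis=1
            )
        return out

    def to_tsv(self, path: str | Path) -> None:
        flat = self.cells.copy()
        flat.columns = [f"{t}|{f}" for t, f in flat.columns]
        flat.insert(0, "anchor_fraction", self.anchor_fraction)
        if self.annotations is not None:
            flat.insert(1, "co2_crossfeeding", self.annotations)
        flat.index.name = "phylotype_id"
        flat.to_csv(path, sep="\t", encoding="utf-8")


def _cell_state(call: LabelCall | None, config: PipelineConfig) -> str:
    if call is None:
        return "unlabeled"
    lp = call.lp
    if lp is None:
        raise ValidationError(
            f"label call for {call.phylotype_id!r} lacks an LP; run "
            "labeling_proportions before building the matrix"
        )
    return "major" if lp >= config.lp_major_pct else "minor"


def build_matrix(
    calls: Iterable[TreatmentCalls],
    anchor: TreatmentKey,
    config: PipelineConfig | None = None,
) -> SubstrateRangeMatrix:
    """Build the substrate-range matrix from per-treatment label calls.

    Rows: phylotypes with status != unlabeled in the anchor treatment, each
    tagged with its anchor fraction of origin (H for labeled, M for weakly
    labeled). Columns: every (treatment, fraction) comparison present in
    ``calls``. Rebuilding from the same calls is bit-identical.
    """
    config = config or PipelineConfig()
    calls = list(calls)
    by_key = {tc.key: tc for tc in calls}
    if anchor not in by_key:
        raise ValidationError(
            f"anchor treatment {anchor.label()!r} absent from the label calls"
        )
    anchor_calls = by_key[anchor]
    rows = sorted(
        pid
        for pid, status in anchor_calls.statuses.items()
        if status.status != "unlabeled"
    )
    anchor_fraction = pd.Series(
        {
            pid: "H" if anchor_calls.statuses[pid].status == "labeled" else "M"
            for pid in rows
        },
        dtype=object,
        name="anchor_fraction",
    ).reindex(rows)
    columns = pd.MultiIndex.from_tuples(
        [(tc.key.label(), frac) for tc in calls for frac in ("H", "M")],
        names=["treatment", "fraction"],
    )
    cells = pd.DataFrame(index=pd.Index(rows, name="phylotype_id"),
                         columns=columns, dtype=object)
    for tc in calls:
        for frac, label_set in (("H", tc.h), ("M", tc.m)):
            for pid in rows:
                cells.loc[pid, (tc.key.label(), frac)] = _cell_state(
                    label_set.get(pid), config
                )
    return SubstrateRangeMatrix(
        anchor=anchor, cells=cells, anchor_fraction=anchor_fraction
    )


def flag_co2_crossfeeding(
    matrix: SubstrateRangeMatrix, calls: Iterable[TreatmentCalls]
) -> SubstrateRangeMatrix:
    """Annotate each row with its CO2 cross-feeding assessment.

    potential_crossfeeder: labeled or weakly labeled in any CO2 treatment;
    negligible: present but unlabeled in all CO2 treatments;
    not_assessable: the dataset has no CO2 treatment.
    """
    co2 = [tc for tc in calls if tc.key.treatment == "co2"]
    if not co2:
        flags = pd.Series(
            "not_assessable", index=matrix.cells.index, dtype=object
        )
    else:
        def flag(pid: str) -> str:
            for tc in co2:
                status = tc.statuses.get(pid)
                if status is not None and status.status in (
                    "labeled",
                    "weakly_labeled",
                ):
                    return "potential_crossfeeder"
            return "negligible"

        flags = pd.Series(
            {pid: flag(pid) for pid in matrix.cells.index}, dtype=object
        ).reindex(matrix.cells.index)
    flags.name = "co2_crossfeeding"
    return SubstrateRangeMatrix(
        anchor=matrix.anchor,
        cells=matrix.cells,
        anchor_fraction=matrix.anchor_fraction,
        annotations=flags,
    )


def plot_matrix(matrix: SubstrateRangeMatrix, path: str | Path) -> None:
    """Render the split-view matrix in the customary black/gray/white scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    rank = {state: i for i, state in enumerate(CELL_STATES)}
    data = matrix.cells.map(lambda s: rank[s]).to_numpy(dtype=float)
    cmap = ListedColormap(["white", "lightgray", "black"])
    n_rows, n_cols = data.shape if data.size else (1, 1)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * n_cols), max(2.5, 0.35 * n_rows))
    )
    if data.size:
        ax.imshow(data, cmap=cmap, vmin=0, vmax=2, aspect="auto")
        ax.set_xticks(range(data.shape[1]))
        ax.set_xticklabels(
            [f"{t}\n{f}" for t, f in matrix.cells.columns], fontsize=6, rotation=90
        )
        ax.set_yticks(range(data.shape[0]))
        ax.set_yticklabels(matrix.cells.index, fontsize=6)
    ax.set_title(
        f"Substrate range (anchor: {matrix.anchor.label()})", fontsize=8
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
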