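"""The four-criterion isotope-label classifier and the labeling proportion (LP).

A phylotype is 'potentially labeled' in a fraction class (H or M) of a
13C treatment when all four of the following hold, with RA denoting relative
abundance in percent:

1. RA in the 13C fraction is higher (strictly) than in the corresponding
   fraction of the 12C control;
2. RA in the 13C light (L) fraction is lower (strictly) than in the 13C
   fraction under test;
3. RA in the 13C fraction is at least 0.5%;
4. the 13C-minus-12C RA difference in the compared fraction class is at
   least 0.1 percentage points.

Criteria 1 and 2 guard against migration of light DNA into heavy fractions;
criteria 3 and 4 impose minimum-signal floors. For the n phylotypes passing
all four in a fraction, the labeling proportion is

    LP_x = 100 * RA_x^13C / sum_i RA_i^13C

— a within-fraction share of the labeled community (the sum runs over the n
potentially labeled phylotypes), not an enrichment estimate. LP >= 5% marks a
taxon of major importance. A phylotype labeled in H is 'labeled'; labeled in
M only, 'weakly labeled' — consistent with partial labeling or with fully
labeled DNA of very low (< 40%) GC content.

Phylotypes absent from a comparison library are assigned RA = 0: absence of
reads is evidence of absence at the measured depth, and skipping them would
bias toward labeling. The procedure is a deliberate threshold rule on pooled
libraries; no replicate-variance model or multiple-testing correction is
layered on top, because that would change the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import pandas as pd

from .tables_io import OtuTable, PipelineConfig, ValidationError

__all__ = [
    "TreatmentKey",
    "CriteriaResult",
    "LabelCall",
    "LabelSet",
    "PhylotypeStatus",
    "TreatmentCalls",
    "evaluate_criteria",
    "call_fraction",
    "labeling_proportions",
    "classify_importance",
    "call_phylotype",
    "call_treatment",
    "treatment_keys",
]

Fraction = Literal["H", "M"]

#: Absolute tolerance for the inclusive thresholds (criteria 3 and 4): decimal
#: percentages such as 0.1 are not exactly representable in binary, and a
#: difference like 5.00 - 4.90 must still count as >= 0.1.
_GE_TOL = 1e-9


@dataclass(frozen=True)
class TreatmentKey:
    """Coordinates of one 13C-vs-12C comparison (isotope pair implied)."""

    marker: str
    experiment: str
    treatment: str
    ph_condition: str = "not_applicable"

    def label(self) -> str:
        parts = [self.experiment, self.treatment]
        if self.ph_condition != "not_applicable":
            parts.append(self.ph_condition)
        return ":".join(parts)


@dataclass(frozen=True)
class CriteriaResult:
    """Outcome of the four criteria for one phylotype in one fraction class."""

    c1: bool
    c2: bool
    c3: bool
    c4: bool
    fraction: Fraction
    ra_13c_frac: float
    ra_12c_frac: float
    ra_13c_light: float

    @property
    def potentially_labeled(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4


@dataclass(frozen=True)
class LabelCall:
    phylotype_id: str
    key: TreatmentKey
    fraction: Fraction
    criteria: CriteriaResult
    lp: float | None = None
    importance: str | None = None  # "major" | "minor" when lp is present


@dataclass
class LabelSet:
    """All label calls for one (treatment, fraction class) comparison.

    ``members`` holds the potentially labeled phylotypes; ``evaluated`` every
    phylotype present in the 13C fraction library (members included).
    """

    key: TreatmentKey
    fraction: Fraction
    members: list[LabelCall] = field(default_factory=list)
    evaluated: list[LabelCall] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def ra_sum(self) -> float:
        """Sum of members' RA (%) in the 13C fraction — the LP denominator."""
        return float(sum(c.criteria.ra_13c_frac for c in self.members))

    @property
    def labeled_sequence_share(self) -> float:
        """Share (%) of the 13C fraction library's reads in labeled phylotypes."""
        return self.ra_sum

    def member_ids(self) -> set[str]:
        return {c.phylotype_id for c in self.members}

    def get(self, phylotype_id: str) -> LabelCall | None:
        for call in self.members:
            if call.phylotype_id == phylotype_id:
                return call
        return None


@dataclass(frozen=True)
class PhylotypeStatus:
    """Per-phylotype verdict for one treatment: labeled / weakly_labeled / unlabeled."""

    phylotype_id: str
    key: TreatmentKey
    status: str
    calls: tuple[LabelCall, ...] = ()


@dataclass
class TreatmentCalls:
    """H and M label sets plus per-phylotype statuses for one treatment."""

    key: TreatmentKey
    h: LabelSet
    m: LabelSet
    statuses: dict[str, PhylotypeStatus] = field(default_factory=dict)


def evaluate_criteria(
    ra_13c_frac: float,
    ra_12c_frac: float,
    ra_13c_light: float,
    fraction: Fraction,
    config: PipelineConfig | None = None,
) -> CriteriaResult:
    """Evaluate the four criteria on an abundance triple (all in percent).

    Strictness follows the printed wording: criteria 1 and 2 are strict
    inequalities ("higher than" / "lower than"), criteria 3 and 4 inclusive
    (">= 0.5%" / ">= 0.1%").
    """
    config = config or PipelineConfig()
    if fraction not in ("H", "M"):
        raise ValidationError(f"fraction must be 'H' or 'M', got {fraction!r}")
    for name, value in (
        ("ra_13c_frac", ra_13c_frac),
        ("ra_12c_frac", ra_12c_frac),
        ("ra_13c_light", ra_13c_light),
    ):
        if not (0.0 <= value <= 100.0):
            raise ValidationError(
                f"{name} must be a percentage in [0, 100], got {value!r}"
            )
    return CriteriaResult(
        c1=ra_13c_frac > ra_12c_frac,
        c2=ra_13c_light < ra_13c_frac,
        c3=ra_13c_frac >= config.min_ra_pct - _GE_TOL,
        c4=(ra_13c_frac - ra_12c_frac) >= config.min_diff_pct - _GE_TOL,
        fraction=fraction,
        ra_13c_frac=ra_13c_frac,
        ra_12c_frac=ra_12c_frac,
        ra_13c_light=ra_13c_light,
    )


def _find_library(table: OtuTable, key: TreatmentKey, isotope: str, pool: str) -> str:
    matches = [
        m.library_id
        for m in table.libraries
        if m.marker == key.marker
        and m.experiment == key.experiment
        and m.treatment == key.treatment
        and m.ph_condition == key.ph_condition
        and m.isotope == isotope
        and m.pool == pool
    ]
    if len(matches) != 1:
        state = "missing" if not matches else "ambiguous"
        raise ValidationError(
            f"{state} pooled library for treatment {key.treatment!r} "
            f"({key.marker}, {key.experiment}, ph={key.ph_condition}), "
            f"isotope {isotope!r}, pool {pool!r}"
        )
    return matches[0]


def _ra_vector(table: OtuTable, library_id: str) -> pd.Series:
    column = table.counts[library_id]
    total = int(column.sum())
    if total == 0:
        return column.astype(float) * 0.0
    return 100.0 * column.astype(float) / float(total)


def call_fraction(
    table: OtuTable,
    key: TreatmentKey,
    fraction: Fraction,
    config: PipelineConfig | None = None,
) -> LabelSet:
    """Evaluate the criteria for every phylotype present in the 13C fraction.

    Requires three pooled libraries in ``table``: the 13C and 12C libraries of
    the named fraction class and the 13C light library; a missing one raises
    an error naming (treatment, isotope, pool). Phylotypes absent from a
    comparison library count as RA 0.
    """
    config = config or PipelineConfig()
    if fraction not in ("H", "M"):
        raise ValidationError(f"fraction must be 'H' or 'M', got {fraction!r}")
    lib_13c = _find_library(table, key, "c13", fraction)
    lib_12c = _find_library(table, key, "c12", fraction)
    lib_13c_l = _find_library(table, key, "c13", "L")
    ra_13c = _ra_vector(table, lib_13c)
    ra_12c = _ra_vector(table, lib_12c)
    ra_13c_l = _ra_vector(table, lib_13c_l)
    present = table.counts[lib_13c] > 0
    label_set = LabelSet(key=key, fraction=fraction)
    for pid in sorted(table.counts.index[present]):
        criteria = evaluate_criteria(
            float(ra_13c[pid]),
            float(ra_12c[pid]),
            float(ra_13c_l[pid]),
            fraction,
            config,
        )
        call = LabelCall(phylotype_id=pid, key=key, fraction=fraction, criteria=criteria)
        label_set.evaluated.append(call)
        if criteria.potentially_labeled:
            label_set.members.append(call)
    return label_set


def labeling_proportions(
    label_set: LabelSet, config: PipelineConfig | None = None
) -> LabelSet:
    """Fill LP (and importance) for every member of the set.

    LP_x = 100 * RA_x / sum_i RA_i over the set's members; the LPs of a
    non-empty set sum to 100. An empty set passes through unchanged.
    """
    config = config or PipelineConfig()
    if label_set.n == 0:
        return label_set
    denom = label_set.ra_sum
    if denom <= 0:
        raise ValidationError(
            "labeled set has zero total relative abundance; cannot normalize"
        )
    members = []
    by_id = {}
    for call in label_set.members:
        # clamp against floating-point overshoot (e.g. 100.00000000000001)
        lp = min(max(100.0 * call.criteria.ra_13c_frac / denom, 0.0), 100.0)
        filled = replace(call, lp=lp, importance=classify_importance(lp, config))
        members.append(filled)
        by_id[filled.phylotype_id] = filled
    evaluated = [by_id.get(c.phylotype_id, c) for c in label_set.evaluated]
    return LabelSet(
        key=label_set.key,
        fraction=label_set.fraction,
        members=members,
        evaluated=evaluated,
    )


def classify_importance(lp: float, config: PipelineConfig | None = None) -> str:
    """Classify a labeling proportion as 'major' (LP >= 5%) or 'minor'."""
    config = config or PipelineConfig()
    if not (0.0 <= lp <= 100.0):
        raise ValidationError(f"lp must be in [0, 100], got {lp!r}")
    return "major" if lp >= config.lp_major_pct else "minor"


def call_phylotype(
    h_set: LabelSet, m_set: LabelSet, phylotype_id: str
) -> PhylotypeStatus:
    """Combine H and M membership into a status for one phylotype.

    Labeled if a member of the H set (both H and M membership still reports
    'labeled', with both calls retained — the H and M LPs are reported side by
    side); weakly labeled if a member of the M set only; unlabeled otherwise.
    """
    if h_set.key != m_set.key:
        raise ValidationError("H and M label sets are for different treatments")
    h_call = h_set.get(phylotype_id)
    m_call = m_set.get(phylotype_id)
    if h_call is not None:
        status = "labeled"
    elif m_call is not None:
        status = "weakly_labeled"
    else:
        status = "unlabeled"
    calls = tuple(c for c in (h_call, m_call) if c is not None)
    return PhylotypeStatus(
        phylotype_id=phylotype_id, key=h_set.key, status=status, calls=calls
    )


def call_treatment(
    table: OtuTable,
    key: TreatmentKey,
    config: PipelineConfig | None = None,
) -> TreatmentCalls:
    """Run both fraction classes for one treatment and derive statuses.

    Statuses cover every phylotype evaluated in either fraction (i.e., present
    in the 13C H or M library).
    """
    config = config or PipelineConfig()
    h_set = labeling_proportions(call_fraction(table, key, "H", config), config)
    m_set = labeling_proportions(call_fraction(table, key, "M", config), config)
    evaluated_ids = sorted(
        {c.phylotype_id for c in h_set.evaluated}
        | {c.phylotype_id for c in m_set.evaluated}
    )
    statuses = {
        pid: call_phylotype(h_set, m_set, pid) for pid in evaluated_ids
    }
    return TreatmentCalls(key=key, h=h_set, m=m_set, statuses=statuses)


def treatment_keys(table: OtuTable) -> list[TreatmentKey]:
    """All treatment keys in a table that have a 13C library (sorted, unique)."""
    keys = {
        TreatmentKey(m.marker, m.experiment, m.treatment, m.ph_condition)
        for m in table.libraries
        if m.isotope == "c13" and m.pool != "unpooled"
    }
    return sorted(keys, key=lambda k: (k.marker, k.experiment, k.treatment, k.ph_condition))
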