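"""Synthetic SIP gradient and community generator with analytic ground truth.

The generator stands in for raw sequencing data and makes every downstream
stage verifiable at desk scale. Its model:

* A community of taxa with log-normal relative abundances, uniform GC content
  and a known 13C atom fraction per taxon (0 = unlabeled, 1 = fully labeled).
* DNA buoyant density is linear in GC content, shifted upward by 13C
  incorporation::

      rho = 1.660 + 0.098 * GC + 0.036 * atom_fraction   [g/ml]

  The intercept/slope follow the classical GC-density relation for CsCl
  gradients, and 0.036 g/ml is the conventional full-labeling shift between
  non-labeled and fully labeled DNA.
* Within a gradient, a taxon's DNA disperses normally (sd ``dispersion_sd``)
  around its mean density and is collected into 10 fractions with fixed
  density edges.
* Sequencing draws ``read_depth`` reads per treatment, allocated jointly
  multinomially over (taxon x fraction) cells in proportion to DNA mass —
  the in-silico analogue of pooling gradient DNA and sequencing it. The 12C
  control shares the identical community with every atom fraction forced
  to zero.

``ground_truth_status`` pushes the infinite-depth expected pooled relative
abundances through the same four criteria the caller applies, yielding the
noise-free expected status per taxon — an analytic oracle for the stochastic
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .gradient_pooling import (
    FractionRecord,
    assign_pool,
    pool_fractions,
    pooled_to_otu_table,
)
from .label_caller import evaluate_criteria
from .tables_io import (
    LibraryMetadata,
    OtuTable,
    PipelineConfig,
    ValidationError,
)

__all__ = [
    "SimTaxon",
    "GradientModel",
    "SimOutput",
    "simulate_community",
    "dna_buoyant_density",
    "fraction_mass",
    "simulate_libraries",
    "ground_truth_status",
    "expected_pool_abundances",
]

#: Default interior fraction edges: 9 edges -> 10 bins, 0.008 g/ml apart,
#: spanning 1.690-1.754 so that bin midpoints cover the L, M and H regions.
DEFAULT_EDGES = tuple(round(1.690 + 0.008 * k, 3) for k in range(9))


@dataclass(frozen=True)
class SimTaxon:
    taxon_id: str
    rel_abundance: float
    gc_content: float
    atom_fraction_13c: float

    @property
    def truly_labeled(self) -> bool:
        return self.atom_fraction_13c > 0.0

    def __post_init__(self) -> None:
        for name in ("rel_abundance", "gc_content", "atom_fraction_13c"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: {name} must be in [0, 1], got {value!r}"
                )


@dataclass(frozen=True)
class GradientModel:
    """Density model, fractionation geometry and sequencing depth.

    ``dispersion_sd`` is the within-gradient standard deviation of a taxon's
    DNA around its mean density; the default 0.0015 g/ml keeps a fully labeled
    mid-GC taxon >= 99.9% inside the heavy window while keeping the heavy-side
    Gaussian tail of fully labeled low-GC (< 40%) DNA — which bands in the
    middle window — small enough that the classifier's 0.5% abundance floor is
    not reached by tail mass alone. ``read_depth`` is the total number of reads
    sequenced per treatment gradient.
    """

    bd_intercept: float = 1.660
    gc_slope: float = 0.098
    full_label_shift: float = 0.036
    dispersion_sd: float = 0.0015
    fraction_edges: tuple[float, ...] = DEFAULT_EDGES
    read_depth: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.fraction_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 1:
            raise ValidationError("fraction_edges must be a non-empty 1-D sequence")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("fraction_edges must be strictly increasing")
        if not self.dispersion_sd > 0:
            raise ValidationError("dispersion_sd must be positive")
        if self.read_depth < 0:
            raise ValidationError("read_depth must be non-negative")

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_edges) + 1

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Nominal density of each fraction (outer bins: edge -/+ half width)."""
        edges = np.asarray(self.fraction_edges, dtype=float)
        half = (edges[1] - edges[0]) / 2.0 if len(edges) > 1 else 0.004
        inner = (edges[:-1] + edges[1:]) / 2.0
        return np.concatenate(([edges[0] - half], inner, [edges[-1] + half]))


@dataclass
class SimOutput:
    """Everything a simulation run produces, plus its ground truth."""

    community: list[SimTaxon]
    model: GradientModel
    fractions: dict[str, list[FractionRecord]]  # isotope -> 10 FractionRecords
    pooled: OtuTable
    truth: dict[str, str]  # taxon_id -> expected status


def simulate_community(
    n_taxa: int,
    n_labeled: int,
    abundance_lognormal_sd: float = 1.0,
    gc_range: tuple[float, float] = (0.40, 0.65),
    atom_fraction: float = 1.0,
    seed: int = 0,
) -> list[SimTaxon]:
    """Draw a community with a known labeled subset; deterministic per seed.

    Abundances are log-normal (normalized to sum to 1), GC content uniform on
    ``gc_range``, and the ``n_labeled`` most abundant taxa receive the stated
    atom fraction — labeling the abundant members keeps the signal observable
    at desk-scale sequencing depths. The default GC range starts at 0.40 (the
    working assumption of the classifier is that genome GC exceeds 40%) and
    stays below the GC content at which unlabeled DNA would reach the heavy
    window under the linear density model.
    """
    if n_labeled > n_taxa:
        raise ValidationError(
            f"n_labeled ({n_labeled}) cannot exceed n_taxa ({n_taxa})"
        )
    if n_taxa < 1:
        raise ValidationError("n_taxa must be >= 1")
    lo, hi = gc_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"gc_range must satisfy 0 <= lo <= hi <= 1, got {gc_range}")
    if not (0.0 <= atom_fraction <= 1.0):
        raise ValidationError("atom_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_lognormal_sd, size=n_taxa)
    abundances = raw / raw.sum()
    gc = rng.uniform(lo, hi, size=n_taxa)
    order = np.argsort(-abundances, kind="stable")
    labeled = set(order[:n_labeled].tolist())
    width = len(str(n_taxa))
    return [
        SimTaxon(
            taxon_id=f"taxon_{i + 1:0{width}d}",
            rel_abundance=float(abundances[i]),
            gc_content=float(gc[i]),
            atom_fraction_13c=atom_fraction if i in labeled else 0.0,
        )
        for i in range(n_taxa)
    ]


def dna_buoyant_density(
    gc: float, atom_fraction: float, model: GradientModel | None = None
) -> float:
    """Mean buoyant density (g/ml) of DNA with the given GC and 13C content."""
    model = model or GradientModel()
    if not (0.0 <= gc <= 1.0):
        raise ValidationError(f"gc must be in [0, 1], got {gc!r}")
    if not (0.0 <= atom_fraction <= 1.0):
        raise ValidationError(f"atom_fraction must be in [0, 1], got {atom_fraction!r}")
    return (
        model.bd_intercept
        + model.gc_slope * gc
        + model.full_label_shift * atom_fraction
    )


def fraction_mass(rho: float, model: GradientModel | None = None) -> np.ndarray:
    """Share of a taxon's DNA mass landing in each of the fractions.

    The mass in bin (e_low, e_high] is Phi((e_high - rho)/sd) -
    Phi((e_low - rho)/sd); the outer bins take the tails, so the shares sum
    to 1 exactly.
    """
    model = model or GradientModel()
    edges = np.asarray(model.fraction_edges, dtype=float)
    cdf = norm.cdf((edges - rho) / model.dispersion_sd)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def _mass_matrix(
    community: Sequence[SimTaxon], model: GradientModel, labeled: bool
) -> np.ndarray:
    """(n_taxa x n_fractions) DNA-mass weights; rows scaled by abundance."""
    weights = np.empty((len(community), model.n_fractions))
    for i, taxon in enumerate(community):
        atom = taxon.atom_fraction_13c if labeled else 0.0
        rho = dna_buoyant_density(taxon.gc_content, atom, model)
        weights[i] = taxon.rel_abundance * fraction_mass(rho, model)
    return weights


def _check_community(community: Sequence[SimTaxon]) -> None:
    if not community:
        raise ValidationError("community is empty")
    total = sum(t.rel_abundance for t in community)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(
            f"community abundances must sum to 1 (got {total!r}); normalize first"
        )
    ids = [t.taxon_id for t in community]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate taxon_id in community")


def simulate_libraries(
    community: Sequence[SimTaxon],
    model: GradientModel | None = None,
    config: PipelineConfig | None = None,
    *,
    marker: str = "16S",
    experiment: str = "substrate_sip",
    treatment: str = "methanol",
    ph_condition: str = "not_applicable",
) -> SimOutput:
    """Simulate the 12C/13C treatment pair: fraction records, pooled tables, truth.

    Both treatments share the identical community; the 12C control forces every
    atom fraction to zero. Reads per treatment total ``model.read_depth``
    exactly and are allocated multinomially over (taxon x fraction) cells in
    proportion to DNA mass. Deterministic per ``model.seed`` with one
    sub-stream per treatment.
    """
    model = model or GradientModel()
    config = config or PipelineConfig()
    _check_community(community)
    midpoints = model.bin_midpoints
    fractions: dict[str, list[FractionRecord]] = {}
    pooled_libraries = []
    for iso_index, (isotope, labeled) in enumerate((("c12", False), ("c13", True))):
        weights = _mass_matrix(community, model, labeled)
        p = weights.ravel()
        p_sum = p.sum()
        if p_sum <= 0:
            counts = np.zeros_like(p, dtype="int64")
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([model.seed, iso_index])
            )
            counts = rng.multinomial(model.read_depth, p / p_sum)
        counts = counts.reshape(weights.shape)
        gradient_id = f"{treatment}_{isotope}"
        records = [
            FractionRecord(
                gradient_id=gradient_id,
                fraction_index=f + 1,
                buoyant_density=float(midpoints[f]),
                counts={
                    taxon.taxon_id: int(counts[i, f])
                    for i, taxon in enumerate(community)
                },
            )
            for f in range(model.n_fractions)
        ]
        fractions[isotope] = records
        meta = LibraryMetadata(
            library_id=gradient_id,
            marker=marker,
            experiment=experiment,
            treatment=treatment,
            isotope=isotope,
            ph_condition=ph_condition,
            pool="H",  # placeholder; pool_fractions rewrites pool and id
        )
        pooled_libraries.extend(pool_fractions(records, meta, config))
    pooled = pooled_to_otu_table(pooled_libraries)
    truth = ground_truth_status(community, model, config)
    return SimOutput(
        community=list(community),
        model=model,
        fractions=fractions,
        pooled=pooled,
        truth=truth,
    )


def expected_pool_abundances(
    community: Sequence[SimTaxon],
    model: GradientModel | None = None,
    config: PipelineConfig | None = None,
    labeled: bool = True,
) -> dict[str, np.ndarray]:
    """Expected relative abundances (%) per pool (H/M/L) at the model's depth.

    Expected DNA-mass weights are summed over each pool's fractions (fractions
    are pooled by the nominal density of their bin midpoint) and renormalized
    within the pool. A pool expected to receive fewer than one read at the
    model's sequencing depth holds no recoverable DNA and yields no library —
    its abundances are all zero, exactly as an empty sequenced pool would
    behave. Without this gate the renormalization of vanishing trace mass
    (e.g. a 12C control's heavy pool) would produce large abundances no
    finite-depth measurement could ever observe.
    """
    model = model or GradientModel()
    config = config or PipelineConfig()
    _check_community(community)
    weights = _mass_matrix(community, model, labeled)
    pools = [assign_pool(bd, config) for bd in model.bin_midpoints]
    grand_total = weights.sum()
    out = {}
    for pool in ("H", "M", "L"):
        cols = [f for f, p in enumerate(pools) if p == pool]
        mass = weights[:, cols].sum(axis=1) if cols else np.zeros(len(community))
        total = mass.sum()
        share = total / grand_total if grand_total > 0 else 0.0
        if total <= 0 or share * model.read_depth < 1.0:
            out[pool] = np.zeros(len(community))
        else:
            out[pool] = 100.0 * mass / total
    return out


def ground_truth_status(
    community: Sequence[SimTaxon],
    model: GradientModel | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Noise-free expected status per taxon via the four criteria.

    Pushes the infinite-depth expected pooled abundances of the 13C and 12C
    treatments through the same classifier the stochastic pipeline uses.
    """
    model = model or GradientModel()
    config = config or PipelineConfig()
    ra_13c = expected_pool_abundances(community, model, config, labeled=True)
    ra_12c = expected_pool_abundances(community, model, config, labeled=False)
    statuses = {}
    for i, taxon in enumerate(community):
        in_h = evaluate_criteria(
            float(ra_13c["H"][i]),
            float(ra_12c["H"][i]),
            float(ra_13c["L"][i]),
            "H",
            config,
        ).potentially_labeled
        in_m = evaluate_criteria(
            float(ra_13c["M"][i]),
            float(ra_12c["M"][i]),
            float(ra_13c["L"][i]),
            "M",
            config,
        ).potentially_labeled
        if in_h:
            statuses[taxon.taxon_id] = "labeled"
        elif in_m:
            statuses[taxon.taxon_id] = "weakly_labeled"
        else:
            statuses[taxon.taxon_id] = "unlabeled"
    return statuses
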