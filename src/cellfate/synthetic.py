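"""Synthetic bulk-RNA-seq cohorts with planted death-mode/cell-type couplings.

The generator emulates the kind of staged brain cohort the pipeline is built
for: TPM-scale bulk expression composed as mixtures of cell-type signatures,
ordered disease-stage labels (BLB0 < BLB5 < BLB6 by default, 28 samples each,
n = 84), and — optionally — stage-specific couplings between a cell-death
gene program and one cell type's abundance.  Every cohort ships with a
``TruthRecord`` (true proportions, signature matrix, planted couplings) so
each downstream stage can be tested against known ground truth.

Model, per sample s in stage t:

    expression_gs = [signature @ proportions_s]_g
                    * 10 ** (beta_c * loading_cg * (p_ks - mean_t(p_k)))   (planted couplings)
                    * lognormal multiplicative noise with CV = noise_cv
    counts_gs ~ Poisson(expression_gs * length_kb_g, scaled to library size)

Couplings act on log-expression, centred within the stage, so they reshape
the covariance between the program's genes and the target cell type's
proportion (what the Mantel stage detects) without shifting the stage-mean
expression.  The per-gene loadings (mean 1) keep the specified shift of the
set's mean log-expression while making genes respond heterogeneously —
a perfectly uniform shift would cancel out of correlation-based
sample-sample distances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCatalog,
    ProportionMatrix,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "DEATH_MODES",
    "DEFAULT_CELL_TYPES",
    "PlantedCoupling",
    "CohortConfig",
    "TruthRecord",
    "SyntheticCohort",
    "make_signature_matrix",
    "simulate_proportions",
    "generate_cohort",
]

#: the five classic cell-death programs modelled throughout
DEATH_MODES: tuple[str, ...] = (
    "apoptosis", "autophagy", "ferroptosis", "necroptosis", "parthanatos",
)

#: ten neural cell types resolved by the deconvolution stage
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "neurons", "astrocytes", "VLMCs", "tanycytes", "OPCs",
    "oligodendrocytes", "ependymal_cells", "endothelial_cells",
    "microglia", "NFOs",
)

#: necroptosis marker genes given their literature names in the catalog
NECROPTOSIS_MARKERS: tuple[str, ...] = ("FAS", "TLR2", "TLR5")
NOS_GENES: tuple[str, ...] = ("NOS1", "NOS2", "NOS3")

#: spread of the per-gene coupling response loadings (mean is fixed at 1)
LOADING_SD = 0.75


@dataclass(frozen=True)
class PlantedCoupling:
    """One planted stage-specific association.

    ``beta`` is the per-unit-proportion shift of the gene set's mean
    log10-expression: in ``stage``, a sample whose ``cell_type`` proportion
    sits delta above the stage mean has the set's mean log10-expression
    shifted by ``beta * delta``.
    """

    stage: str
    death_mode: str  # any catalog set name, including "nos"
    cell_type: str
    beta: float


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort."""

    n_samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"BLB0": 28, "BLB5": 28, "BLB6": 28})
    n_genes_background: int = 500
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    genes_per_death_set: int = 20
    dirichlet_concentration: Sequence[float] | float = 2.0
    coupling_specs: tuple[PlantedCoupling, ...] = ()
    noise_cv: float = 0.1
    library_size_mean: float = 2e7
    count_noise: str = "poisson"  # "poisson" | "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples_per_stage) < 2:
            raise ValidationError("need at least 2 stages")
        if len(self.cell_types) < 2:
            raise ValidationError("need at least 2 cell types")
        conc = self.concentration_vector()
        if (conc <= 0).any():
            raise ValidationError("Dirichlet concentrations must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.count_noise not in ("poisson", "none"):
            raise ValidationError(f"unknown count_noise {self.count_noise!r}")
        self.coupling_specs = tuple(self.coupling_specs)

    def concentration_vector(self) -> np.ndarray:
        conc = self.dirichlet_concentration
        if np.isscalar(conc):
            return np.full(len(self.cell_types), float(conc))
        conc = np.asarray(conc, float)
        if conc.shape != (len(self.cell_types),):
            raise ValidationError("concentration length must match cell_types")
        return conc

    @property
    def stage_order(self) -> tuple[str, ...]:
        return tuple(self.n_samples_per_stage)


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort — the recovery-test oracle."""

    true_proportions: ProportionMatrix
    signature_matrix: pd.DataFrame  # gene x cell-type, TPM-scale
    couplings: tuple[PlantedCoupling, ...]
    rng_seed: int


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix
    metadata: SampleMetadata
    annotation: GeneAnnotation
    catalog: GeneSetCatalog
    truth: TruthRecord


def make_signature_matrix(n_genes: int, cell_types: Sequence[str],
                          rng_seed: int) -> pd.DataFrame:
    """Cell-type signature with disjoint marker blocks per type.

    Each cell type receives a block of marker genes whose expression is at
    least five-fold the gene's background mean across the other types, which
    guarantees the mixing model is identifiable for the deconvolution stage.
    Deterministic given the seed.
    """
    cell_types = list(cell_types)
    k = len(cell_types)
    if n_genes < k:
        raise ValidationError(f"need >= {k} genes for {k} cell types, got {n_genes}")
    rng = np.random.default_rng(rng_seed)
    base = rng.lognormal(mean=np.log(50.0), sigma=0.7, size=n_genes)
    values = base[:, None] * rng.uniform(0.7, 1.3, size=(n_genes, k))
    block = max(1, min(8, n_genes // (2 * k)))
    for t in range(k):
        rows = slice(t * block, (t + 1) * block)
        folds = rng.uniform(6.0, 12.0, size=block)
        others = np.delete(values[rows], t, axis=1).mean(axis=1)
        values[rows, t] = folds * others
    index = [f"G{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(values, index=index, columns=cell_types)


def simulate_proportions(n_samples: int, concentration: Sequence[float],
                         rng_seed: int,
                         cell_types: Sequence[str] | None = None,
                         sample_ids: Sequence[str] | None = None) -> ProportionMatrix:
    """Draw sample compositions from a Dirichlet law on the simplex."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    conc = np.asarray(concentration, float)
    if (conc <= 0).any():
        raise ValidationError("Dirichlet concentrations must be > 0")
    rng = np.random.default_rng(rng_seed)
    values = rng.dirichlet(conc, size=n_samples)
    if cell_types is None:
        cell_types = [f"type{j}" for j in range(len(conc))]
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    return ProportionMatrix(pd.DataFrame(values, index=list(sample_ids),
                                         columns=list(cell_types)))


def _child_seed(rng_seed: int, *tokens) -> int:
    """Stable sub-seed from the cohort seed and a label, independent of
    draw order (adding one coupling never perturbs another's loadings)."""
    digest = hashlib.sha256(repr((rng_seed, *tokens)).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _program_gene_names(mode: str, n: int) -> list[str]:
    names = [f"{mode.upper()}_{i + 1:03d}" for i in range(n)]
    if mode == "necroptosis":
        for i, marker in enumerate(NECROPTOSIS_MARKERS[: min(3, n)]):
            names[i] = marker
    return names


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort: counts, metadata, annotation, catalog, truth.

    Byte-identical output for identical config (including seed).  Separate
    child RNG streams drive the signature, proportions, noise, counts and
    each coupling's loadings, so planted couplings only ever touch the
    targeted set's rows in the targeted stage's columns.
    """
    cell_types = list(config.cell_types)
    stage_order = config.stage_order

    # ---- gene universe: cell-type signature block + death/NOS programs
    signature_bg = make_signature_matrix(
        config.n_genes_background, cell_types,
        rng_seed=_child_seed(config.rng_seed, "signature"))

    rng_prog = np.random.default_rng(_child_seed(config.rng_seed, "programs"))
    catalog = GeneSetCatalog()
    program_genes: list[str] = []
    for mode in DEATH_MODES:
        names = _program_gene_names(mode, config.genes_per_death_set)
        catalog.add(mode, names, role="death_mode",
                    description=f"core {mode} program genes (synthetic)")
        program_genes.extend(names)
    catalog.add("nos", list(NOS_GENES), role="nos",
                description="nitric oxide synthase family")
    catalog.add("necroptosis_markers", list(NECROPTOSIS_MARKERS), role="marker",
                description="necroptosis marker genes")
    program_genes.extend(NOS_GENES)

    base_prog = rng_prog.lognormal(mean=np.log(80.0), sigma=0.5,
                                   size=len(program_genes))
    # program genes express uniformly across cell types: their association
    # with any cell type comes only from planted couplings
    signature_prog = pd.DataFrame(
        np.repeat(base_prog[:, None], len(cell_types), axis=1),
        index=program_genes, columns=cell_types)
    signature = pd.concat([signature_bg, signature_prog])

    # ---- annotation: lengths + a sprinkling of lncRNA background genes
    rng_anno = np.random.default_rng(_child_seed(config.rng_seed, "annotation"))
    lengths = np.maximum(
        200, rng_anno.lognormal(np.log(1500.0), 0.4, size=len(signature))
    ).astype(int)
    biotype = np.array(["protein_coding"] * len(signature), dtype=object)
    n_lnc = int(0.05 * config.n_genes_background)
    lnc_rows = rng_anno.choice(config.n_genes_background, size=n_lnc, replace=False)
    biotype[lnc_rows] = "lncRNA"
    annotation = GeneAnnotation(pd.DataFrame(
        {"biotype": biotype, "length_bp": lengths}, index=signature.index))

    # ---- per-stage compositions
    conc = config.concentration_vector()
    prop_frames, stage_labels, sample_ids = [], [], []
    for stage in stage_order:
        n_s = int(config.n_samples_per_stage[stage])
        ids = [f"{stage}_S{i:02d}" for i in range(n_s)]
        props = simulate_proportions(
            n_s, conc, rng_seed=_child_seed(config.rng_seed, "proportions", stage),
            cell_types=cell_types, sample_ids=ids)
        prop_frames.append(props.data)
        stage_labels.extend([stage] * n_s)
        sample_ids.extend(ids)
    proportions = ProportionMatrix(pd.concat(prop_frames))
    metadata = SampleMetadata(
        pd.DataFrame({
            "stage": stage_labels,
            "group": (np.array(stage_labels) != stage_order[0]).astype(int),
        }, index=sample_ids),
        stage_order=stage_order)

    # ---- mixture on TPM scale
    expression = signature.to_numpy() @ proportions.values.T  # gene x sample

    # ---- planted couplings on centred log10 expression
    gene_pos = {g: i for i, g in enumerate(signature.index)}
    for coupling in config.coupling_specs:
        if coupling.death_mode not in catalog:
            raise ValidationError(f"coupling references unknown set {coupling.death_mode!r}")
        if coupling.cell_type not in cell_types:
            raise ValidationError(f"coupling references unknown cell type {coupling.cell_type!r}")
        if coupling.stage not in stage_order:
            raise ValidationError(f"coupling references unknown stage {coupling.stage!r}")
        if not np.isfinite(coupling.beta):
            raise ValidationError("coupling beta must be finite")
        set_genes = catalog[coupling.death_mode]
        rows = np.array([gene_pos[g] for g in set_genes])
        cols = np.array([i for i, s in enumerate(stage_labels) if s == coupling.stage])
        rng_c = np.random.default_rng(_child_seed(
            config.rng_seed, "coupling", coupling.stage, coupling.death_mode,
            coupling.cell_type))
        loadings = rng_c.normal(1.0, LOADING_SD, size=len(rows))
        p = proportions.data.iloc[cols][coupling.cell_type].to_numpy()
        delta = coupling.beta * (p - p.mean())
        expression[np.ix_(rows, cols)] *= 10.0 ** np.outer(loadings, delta)

    # ---- multiplicative log-normal noise
    if config.noise_cv > 0:
        rng_noise = np.random.default_rng(_child_seed(config.rng_seed, "noise"))
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        expression = expression * rng_noise.lognormal(
            -sigma ** 2 / 2.0, sigma, size=expression.shape)

    # ---- counts: expected reads proportional to expression x length.
    # The depth scale is a constant computed from lengths alone (not the
    # realized expression), so planted couplings stay local to their set's
    # rows; library sizes then vary naturally around library_size_mean.
    lam = expression * (lengths[:, None] / 1e3)
    lam = lam * (config.library_size_mean / (1e6 * float(np.mean(lengths) / 1e3)))
    if config.count_noise == "poisson":
        rng_counts = np.random.default_rng(_child_seed(config.rng_seed, "counts"))
        count_values = rng_counts.poisson(lam).astype(float)
    else:
        count_values = lam
    counts = ExpressionMatrix(
        pd.DataFrame(count_values, index=signature.index, columns=sample_ids),
        unit_kind="counts")

    truth = TruthRecord(true_proportions=proportions, signature_matrix=signature,
                        couplings=config.coupling_specs, rng_seed=config.rng_seed)
    return SyntheticCohort(counts=counts, metadata=metadata, annotation=annotation,
                           catalog=catalog, truth=truth)
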