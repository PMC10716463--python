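"""Synthetic multi-platform single-cell datasets and pseudo-bulk cohorts.

The generator emulates the kind of data the pipeline is built for: several
single-cell datasets per tumor type, some droplet-based (UMI counts drawn
as negative-binomial with Bernoulli dropout), some full-length (TPM built
from exponentiated Gaussian programs), with planted cell types, a
microglia/macrophage pair that shares a conserved core-gene program across
platforms while its canonical markers suffer droplet-specific dropout, and
pseudo-bulk cohorts with planted immune-stromal-tumor archetypes and
exponential survival times.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``SimulationConfig.seed``, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DROPLET, FULL_LENGTH, BulkCohort, ExpressionDataset

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3",
    "MT-ATP6", "MT-ATP8", "MT-CYB", "MT-ND4", "MT-ND5",
]
CYCLE_GENES = [
    "MKI67", "TOP2A", "CCNB1", "CCNA2", "CDK1",
    "BUB1", "PLK1", "AURKA", "UBE2C", "BIRC5",
]
HSP_GENES = [
    "HSPA1A", "HSPA1B", "HSPA8", "HSP90AA1", "HSP90AB1",
    "HSPB1", "DNAJB1", "HSPD1", "HSPE1", "HSPH1",
]


@dataclass
class CellTypeProgram:
    """Mean expression program of one planted cell type.

    ``markers`` are up-regulated by ``marker_log2fc`` in this type only;
    a ``parent`` program's markers are inherited at half effect (used for
    subsets such as MG/BMDM inside the myeloid compartment).
    """

    name: str
    markers: list[str]
    marker_log2fc: float = 3.0
    parent: str | None = None


@dataclass
class DatasetSpec:
    name: str
    platform: str
    tumor_type: str
    n_cells: int
    proportions: dict[str, float]
    n_donors: int = 2
    qc_violations: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"dataset {self.name!r}: n_cells must be positive")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"dataset {self.name!r}: proportions sum to {total}, not 1")


@dataclass
class SimulationConfig:
    """All knobs of the single-cell generator; ``seed`` fixes every draw."""

    datasets: list[DatasetSpec]
    programs: dict[str, CellTypeProgram]
    seed: int = 0
    n_background: int = 400
    dispersion: float = 0.5          # NB: var = mu + dispersion * mu^2
    dropout: dict = field(default_factory=lambda: {DROPLET: 0.10, FULL_LENGTH: 0.05})
    fragile_genes: list[str] = field(default_factory=list)
    fragile_extra_dropout: float = 0.85   # added to droplet dropout on fragile genes
    droplet_lib_size: float = 6000.0
    lib_sigma: float = 0.25
    mito_fraction: float = 0.04
    fulllength_sigma: float = 0.5
    assignment: str = "exact"             # "exact" or "multinomial"
    baseline_sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.assignment not in ("exact", "multinomial"):
            raise ValueError("assignment must be 'exact' or 'multinomial'")
        for spec in self.datasets:
            missing = set(spec.proportions) - set(self.programs)
            if missing:
                raise ValueError(f"dataset {spec.name!r} references unknown programs {missing}")


def default_programs() -> tuple[dict[str, CellTypeProgram], list[str]]:
    """Canonical cell-type programs for brain-tumor TME emulation.

    Returns the programs and the list of droplet-fragile genes (canonical
    MG/BMDM markers that drop out on the droplet platform while the core
    programs stay detectable).
    """
    mg_core = [f"MGCORE{i:02d}" for i in range(1, 11)]
    bm_core = [f"BMCORE{i:02d}" for i in range(1, 11)]

    def module(prefix: str, n: int = 15) -> list[str]:
        # auxiliary program genes: real cell types differ in many genes
        # beyond their canonical markers
        return [f"{prefix}PRG{i:02d}" for i in range(1, n + 1)]

    programs = {
        "T": CellTypeProgram(
            "T", ["PTPRC", "CD3D", "CD3E", "CD2", "TRAC", "IL7R"] + module("T")),
        "CD4_T": CellTypeProgram(
            "CD4_T", ["CD4", "CCR7", "MAL"] + module("CD4"), parent="T"),
        "CD8_T": CellTypeProgram(
            "CD8_T", ["CD8A", "CD8B", "GZMK", "NKG7"] + module("CD8"), parent="T"),
        "B": CellTypeProgram("B", ["CD79A", "MS4A1", "IGHM"] + module("B")),
        "NK": CellTypeProgram("NK", ["KLRB1", "KLRD1", "GNLY"] + module("NK")),
        "Myeloid": CellTypeProgram(
            "Myeloid", ["ITGAM", "LYZ", "AIF1", "CSF1R"] + module("MYE")),
        "MG": CellTypeProgram(
            "MG", ["P2RY12", "TMEM119", "CX3CR1", "SALL1"] + mg_core, parent="Myeloid"
        ),
        "BMDM": CellTypeProgram(
            "BMDM", ["TGFBI", "ITGA4", "F13A1", "CD163"] + bm_core, parent="Myeloid"
        ),
        "Oligo": CellTypeProgram(
            "Oligo", ["MBP", "MOG", "PLP1", "MAG", "CNP"] + module("OG")),
        "Tumor": CellTypeProgram(
            "Tumor", ["SOX2", "OTX2", "GLI2", "NPR3"] + module("TUM")),
    }
    fragile = ["P2RY12", "TMEM119", "CX3CR1", "SALL1", "TGFBI", "ITGA4", "F13A1", "CD163"]
    return programs, fragile


# ---------------------------------------------------------------------------
# gene universe and per-type profiles
# ---------------------------------------------------------------------------

def _gene_universe(config: SimulationConfig) -> list[str]:
    named: list[str] = []
    for prog in config.programs.values():
        for g in prog.markers:
            if g not in named:
                named.append(g)
    families = MITO_GENES + [f"RPL{i}" for i in range(1, 11)] + [f"RPS{i}" for i in range(1, 11)]
    families += CYCLE_GENES + HSP_GENES
    background = [f"BG{i:04d}" for i in range(1, config.n_background + 1)]
    universe = []
    for g in named + families + background:
        if g not in universe:
            universe.append(g)
    return universe


def _type_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Relative (sum-1) expression profiles per planted type over the universe."""
    genes = _gene_universe(config)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    ribo = np.array([g.startswith(("RPL", "RPS")) for g in genes])
    base[ribo] *= 4.0  # ribosomal genes are abundant in real cells
    # markers are, by definition, genes well expressed in their cell type:
    # floor their baseline so the planted programs are detectable
    marker_union = {g for prog in config.programs.values() for g in prog.markers}
    marker_mask = np.array([g in marker_union for g in genes])
    base[marker_mask] = np.maximum(base[marker_mask], np.median(base))
    # pin the mitochondrial mass to the target fraction
    mito = np.array([g.startswith("MT-") for g in genes])
    non_mito_sum = base[~mito].sum()
    base[mito] = (config.mito_fraction / (1 - config.mito_fraction)) * non_mito_sum / mito.sum()

    def effect_vector(prog: CellTypeProgram) -> np.ndarray:
        boost = np.ones(n)
        if prog.parent is not None:
            parent = config.programs[prog.parent]
            for g in parent.markers:
                boost[idx[g]] *= 2.0 ** (parent.marker_log2fc / 2.0)
        for g in prog.markers:
            boost[idx[g]] *= 2.0 ** prog.marker_log2fc
        return boost

    profiles = {}
    for name, prog in config.programs.items():
        p = base * effect_vector(prog)
        profiles[name] = p / p.sum()
    return genes, profiles


def _assign_types(spec: DatasetSpec, mode: str, rng: np.random.Generator) -> np.ndarray:
    types = list(spec.proportions)
    if mode == "exact":
        counts = np.floor(np.array([spec.proportions[t] for t in types]) * spec.n_cells).astype(int)
        # distribute the rounding remainder to the largest fractional parts
        frac = np.array([spec.proportions[t] for t in types]) * spec.n_cells - counts
        for i in np.argsort(-frac)[: spec.n_cells - counts.sum()]:
            counts[i] += 1
        labels = np.repeat(types, counts)
    else:
        labels = rng.choice(types, size=spec.n_cells,
                            p=[spec.proportions[t] for t in types])
    return np.asarray(labels, dtype=object)


def _plant_qc_violations(matrix: np.ndarray, genes: list[str], n_violations: int,
                         rng: np.random.Generator) -> None:
    """Force the first ``n_violations`` cells to fail one QC gate each (in place)."""
    mito_cols = np.array([g.startswith("MT-") for g in genes])
    for i in range(n_violations):
        kind = i % 3
        row = matrix[i]
        if kind == 0:  # low library: thin counts to ~600 total
            total = row.sum()
            if total > 0:
                matrix[i] = rng.binomial(row.astype(int), min(1.0, 600.0 / total))
        elif kind == 1:  # few detected genes: keep the 150 most expressed only
            order = np.argsort(-row)
            kill = order[150:]
            row[kill] = 0
        else:  # high mitochondrial load: scale MT- counts to ~30% of the cell
            m = row[mito_cols].sum()
            rest = row[~mito_cols].sum()
            if m > 0:
                k = 0.30 * rest / (0.70 * m)
                row[mito_cols] = np.round(row[mito_cols] * k)


def simulate_single_cell(config: SimulationConfig) -> list[ExpressionDataset]:
    """Generate every dataset in the config from one seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    genes, profiles = _type_profiles(config, rng)
    gene_arr = np.asarray(genes, dtype=object)
    fragile_mask = np.isin(gene_arr.astype(str), config.fragile_genes)

    out: list[ExpressionDataset] = []
    for spec in config.datasets:
        labels = _assign_types(spec, config.assignment, rng)
        n, g = spec.n_cells, len(genes)
        drop = config.dropout.get(spec.platform, 0.0)
        if spec.platform == DROPLET:
            d_gene = np.full(g, drop)
            d_gene[fragile_mask] = np.minimum(0.999, drop + config.fragile_extra_dropout)
            lib = rng.lognormal(np.log(config.droplet_lib_size), config.lib_sigma, size=n)
            matrix = np.zeros((n, g))
            for t in dict.fromkeys(labels):
                rows = np.where(labels == t)[0]
                mu = np.outer(lib[rows], profiles[t])
                if config.dispersion > 0:
                    shape = 1.0 / config.dispersion
                    lam = rng.gamma(shape, mu * config.dispersion)
                else:
                    lam = mu
                matrix[rows] = rng.poisson(lam)
            if d_gene.max() > 0:
                keep = rng.random((n, g)) >= d_gene[None, :]
                matrix *= keep
            if spec.qc_violations:
                _plant_qc_violations(matrix, genes, spec.qc_violations, rng)
        else:
            d_gene = np.full(g, drop)
            log2_mu = np.zeros((n, g))
            for t in dict.fromkeys(labels):
                rows = np.where(labels == t)[0]
                log2_mu[rows] = np.log2(profiles[t] * 1e6 + 1e-12)[None, :]
            if config.fulllength_sigma > 0:
                log2_mu = log2_mu + rng.normal(0.0, config.fulllength_sigma, size=(n, g))
            matrix = np.exp2(log2_mu)
            if d_gene.max() > 0:
                keep = rng.random((n, g)) >= d_gene[None, :]
                matrix *= keep
            totals = matrix.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            matrix = matrix / totals * 1e6  # per-cell TPM rescale, stored pre-log

        donors = np.array([f"{spec.name}-d{i % spec.n_donors}" for i in range(n)], dtype=object)
        out.append(
            ExpressionDataset(
                matrix=matrix,
                gene_ids=gene_arr.copy(),
                cell_ids=np.array([f"{spec.name}:c{i:05d}" for i in range(n)], dtype=object),
                platform=spec.platform,
                tumor_type=spec.tumor_type,
                donor=donors,
                cell_label=labels,
                name=spec.name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pseudo-bulk cohorts with planted archetypes
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeSpec:
    """One planted archetype: cellular composition, survival hazard, private genes."""

    name: str
    n_samples: int
    composition: dict[str, float]         # weights over program names
    hazard: float = 0.02                  # exponential event rate per month
    exclusive_genes: list[str] = field(default_factory=list)
    exclusive_log2fc: float = 3.0
    tumor_type: str = "mixed"

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError(f"archetype {self.name!r} has an empty composition")
        if self.n_samples <= 0:
            raise ValueError(f"archetype {self.name!r}: n_samples must be positive")


@dataclass
class BulkPlan:
    archetypes: list[ArchetypeSpec]
    noise_sd: float = 0.3                 # Gaussian noise on log2 expression
    censor_hazard: float = 0.01           # independent exponential censoring

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise ValueError("archetype plan is empty")


def simulate_bulk_cohort(config: SimulationConfig, plan: BulkPlan) -> BulkCohort:
    """Pseudo-bulk cohort: per-sample mixtures of cell-type programs.

    Each sample's linear expression is the archetype's composition-weighted
    mixture of the single-cell programs (with the archetype's private genes
    boosted), log2-transformed with additive Gaussian noise. Survival times
    are exponential with the archetype's hazard under independent
    exponential censoring.
    """
    rng = np.random.default_rng(config.seed + 1)  # offset: independent of the sc stream
    genes, profiles = _type_profiles(config, np.random.default_rng(config.seed))
    idx = {g: i for i, g in enumerate(genes)}

    cols, rows_meta, exprs = [], [], []
    for arch in plan.archetypes:
        missing = set(arch.composition) - set(profiles)
        if missing:
            raise ValueError(f"archetype {arch.name!r} references unknown programs {missing}")
        w = np.array(list(arch.composition.values()), dtype=float)
        w = w / w.sum()
        mix = np.zeros(len(genes))
        for weight, prog in zip(w, arch.composition):
            mix += weight * profiles[prog]
        for g in arch.exclusive_genes:
            if g not in idx:
                raise KeyError(f"exclusive gene {g!r} not in the simulated gene universe")
            mix[idx[g]] *= 2.0 ** arch.exclusive_log2fc
        log2_mu = np.log2(mix * 1e6 + 1)
        for s in range(arch.n_samples):
            expr = log2_mu + rng.normal(0.0, plan.noise_sd, size=len(genes))
            exprs.append(np.maximum(expr, 0.0))
            event_time = rng.exponential(1.0 / arch.hazard)
            censor_time = (rng.exponential(1.0 / plan.censor_hazard)
                           if plan.censor_hazard > 0 else np.inf)
            t = max(min(event_time, censor_time), 1e-3)
            cols.append(f"{arch.name}:s{s:04d}")
            rows_meta.append(
                {"tumor_type": arch.tumor_type, "time_months": t,
                 "event": int(event_time <= censor_time), "archetype_truth": arch.name}
            )
    expression = pd.DataFrame(np.column_stack(exprs), index=genes, columns=cols)
    samples = pd.DataFrame(rows_meta, index=cols)
    return BulkCohort(expression=expression, samples=samples)


# ---------------------------------------------------------------------------
# tumor pseudobulk with planted immune-recruitment programs
# ---------------------------------------------------------------------------

def simulate_ir_pseudobulk(
    n_samples: int = 40,
    n_positive: int = 15,
    n_negative: int = 15,
    n_null: int = 300,
    effect: float = 2.0,
    noise_sd: float = 0.4,
    seed: int = 0,
):
    """Tumor-cell pseudobulk whose planted programs track immune content.

    Immune content (the CD45 proxy) is uniform across samples; positive-IR
    genes increase linearly with it, negative-IR genes decrease, null genes
    are pure noise. Returns ``(expression genes x samples, immune_content,
    positive_truth, negative_truth)``.
    """
    rng = np.random.default_rng(seed)
    immune = rng.uniform(0.05, 0.95, size=n_samples)
    pos = [f"IRP{i:03d}" for i in range(1, n_positive + 1)]
    neg = [f"IRN{i:03d}" for i in range(1, n_negative + 1)]
    null = [f"NUL{i:04d}" for i in range(1, n_null + 1)]
    base = 5.0
    rows = []
    for _ in pos:
        rows.append(base + effect * immune + rng.normal(0, noise_sd, n_samples))
    for _ in neg:
        rows.append(base + effect * (1 - immune) + rng.normal(0, noise_sd, n_samples))
    for _ in null:
        rows.append(base + rng.normal(0, noise_sd, n_samples))
    cols = [f"s{i:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(np.vstack(rows), index=pos + neg + null, columns=cols)
    immune_content = pd.Series(immune, index=cols, name="immune_content")
    return expr, immune_content, pos, neg
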