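"""Simulation configuration, seed bookkeeping and benchmark designs.

A :class:`SimulationConfig` drives one end-to-end repertoire simulation:
germline customization (novel-allele injection), independent V(D)J
rearrangement, optional SHM maturation with clonal expansion, and
paired-end read generation.  :func:`build_design` expands a benchmark
design — varying gene expression (DEXPR), minor-allele ratio (DALLELE),
SNP count (DSNP) or SHM load (DSHM) across groups of replicates — into a
list of per-repertoire configs with derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures
from .germline import GermlineDatabase, inject_artificial_snps, prune_confusable
from .maturation import (
    ClonalSizeModel,
    CloneLineage,
    LineageMember,
    expand_lineages,
    grow_lineages,
)
from .reads import ReadPair, ReadProfile, generate_reads, write_fastq
from .rearrange import JunctionModel, UsageModel, simulate_rearrangements

__all__ = [
    "SimulationConfig",
    "DatasetDesign",
    "SimulationResult",
    "child_seeds",
    "compute_read_budget",
    "build_design",
    "run_simulation",
    "DESIGN_LEVELS",
]

#: Studied-variable levels per benchmark design.  Expression in percent of
#: clones, minor-allele ratio in percent within the gene, SNP counts per
#: novel allele, SHM as off/on.
DESIGN_LEVELS = {
    "DEXPR": {"variable": "expression_pct", "levels": (5.0, 1.0, 0.1, 0.01)},
    "DALLELE": {"variable": "minor_ratio_pct", "levels": (50.0, 30.0, 10.0, 5.0)},
    "DSNP": {"variable": "n_snps", "levels": (1, 3, 5, 7)},
    "DSHM": {"variable": "shm", "levels": ("off", "on")},
}


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Splitting rule: ``SeedSequence(master).spawn(n)``, each child reduced
    to one 31-bit state word, so every stage/replicate is independently
    reproducible from the master seed alone.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def compute_read_budget(
    base_reads_millions: float, base_maf: float, target_maf: float
) -> float:
    """Reads (millions) keeping novel-allele read support constant.

    Lowering the minor-allele fraction by a factor k multiplies the read
    budget by k, so every group's novel allele is covered by the same
    number of reads: ``base_reads * base_maf / target_maf``.
    """
    if not (0 < base_maf <= 1) or not (0 < target_maf <= 1):
        raise ValueError("minor-allele fractions must lie in (0, 1]")
    if base_reads_millions <= 0:
        raise ValueError("base_reads_millions must be > 0")
    return base_reads_millions * base_maf / target_maf


@dataclass
class SimulationConfig:
    """Every knob of one repertoire simulation (fixed seed => fixed bytes).

    File-path fields may be ``None``, in which case the synthetic fixture
    models are used.
    """

    # inputs (None -> synthetic fixtures)
    germline_fasta: str | None = None
    usage_tsv: str | None = None
    junction_tsv: str | None = None
    mutability_tsv: str | None = None
    substitution_tsv: str | None = None
    # toy germline shape when no FASTA is given
    n_v: int = 48
    n_d: int = 5
    n_j: int = 6
    v_length: int = 296
    # novel-allele injection
    inject_targets: tuple[str, ...] = ()
    n_snps: int = 1
    # studied-variable controls
    target_gene: str | None = None
    target_usage_pct: float | None = None
    allele_ratio_gene: str | None = None
    minor_ratio: float | None = None
    # rearrangement
    n_rearrangements: int = 1000
    productive_fraction: float | None = 1.0
    # maturation (iterations = 0 disables SHM)
    shm: bool = False
    iterations: int = 5
    select_fraction: float = 0.3
    mut_ability_fold: float = fixtures.DEFAULT_MUT_ABILITY_FOLD
    alpha: float = 2.0
    max_size: int = 50
    max_sequences: int | None = None
    # reads
    n_reads: int = 10_000
    read_length: int = 250
    # reproducibility
    seed: int = 0
    label: str = "sim"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "inject_targets" in data:
            data["inject_targets"] = tuple(data["inject_targets"])
        return cls(**data)


@dataclass
class DatasetDesign:
    """One benchmark design: a studied variable, its levels, replicates."""

    name: str
    levels: tuple = ()
    replicates: int = 5

    def __post_init__(self):
        if self.name not in DESIGN_LEVELS:
            raise ValueError(
                f"unknown design {self.name!r}; expected one of {list(DESIGN_LEVELS)}"
            )
        if not self.levels:
            self.levels = DESIGN_LEVELS[self.name]["levels"]


def _usage_with_target(
    db: GermlineDatabase, target_gene: str, usage_pct: float
) -> UsageModel:
    """Uniform usage except the target gene, pinned at ``usage_pct``%."""
    v_alleles = db.by_segment("V")
    target = [a for a in v_alleles if a.gene == target_gene]
    others = [a for a in v_alleles if a.gene != target_gene]
    if not target:
        raise ValueError(f"gene {target_gene} has no V alleles in the database")
    p = usage_pct / 100.0
    usage_v = {a.name: p / len(target) for a in target}
    usage_v.update({a.name: (1 - p) / len(others) for a in others})
    usage = {
        "V": usage_v,
        "D": {a.name: 1.0 for a in db.by_segment("D")},
        "J": {a.name: 1.0 for a in db.by_segment("J")},
    }
    return UsageModel(usage)


def build_design(
    design: DatasetDesign | str, base: SimulationConfig | None = None
) -> list[SimulationConfig]:
    """Expand a design into one config per repertoire replicate.

    All non-studied variables sit at the level most favourable to novel
    allele detection (single SNP, ~5% target-gene expression, no SHM, 1 M
    read budget); the studied variable takes the group's level.  Replicate
    seeds are derived from the base config's master seed.
    """
    if isinstance(design, str):
        design = DatasetDesign(design)
    base = base or SimulationConfig()
    configs: list[SimulationConfig] = []
    n_groups = len(design.levels)
    seeds = child_seeds(base.seed, n_groups * design.replicates)
    k = 0
    for level in design.levels:
        for rep in range(design.replicates):
            cfg = dataclasses.replace(
                base,
                seed=seeds[k],
                label=f"{design.name}_{level}_rep{rep}",
                target_gene=base.target_gene or "IGHV1-S",
                target_usage_pct=5.0,
                n_snps=1,
                shm=False,
                n_reads=base.n_reads,
            )
            if design.name == "DEXPR":
                cfg.target_usage_pct = float(level)
            elif design.name == "DALLELE":
                cfg.allele_ratio_gene = cfg.target_gene
                cfg.minor_ratio = float(level) / 100.0
                # base.n_reads is the 50%-ratio group's budget; other
                # groups scale so novel-allele read support stays constant.
                cfg.n_reads = int(
                    round(
                        base.n_reads
                        * compute_read_budget(1.0, 0.50, float(level) / 100.0)
                    )
                )
            elif design.name == "DSNP":
                cfg.n_snps = int(level)
            elif design.name == "DSHM":
                cfg.shm = level == "on"
            configs.append(cfg)
            k += 1
    return configs


@dataclass
class SimulationResult:
    """Everything one simulation produced, with full truth provenance."""

    config: SimulationConfig
    reference: GermlineDatabase  # customized (post-injection, pruned)
    truths: list  # NovelAlleleTruth
    rearrangements: list
    lineages: list[CloneLineage]
    pool_sequences: list[str]
    pool_weights: list[int]


def run_simulation(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    write_reads: bool = True,
) -> SimulationResult:
    """Run one full simulation from a config.

    Stage seeds derive from ``config.seed`` via :func:`child_seeds` in the
    fixed order (germline, injection, rearrangement, maturation,
    expansion, reads).  With ``outdir`` set, writes the customized
    reference, truth tables and paired FASTQ files there.
    """
    (
        s_germ,
        s_inject,
        s_rearr,
        s_mature,
        s_expand,
        s_reads,
    ) = child_seeds(config.seed, 6)

    # --- reference -----------------------------------------------------
    if config.germline_fasta:
        from .germline import load_germline_fasta

        db = load_germline_fasta(config.germline_fasta)
    else:
        db = fixtures.generate_toy_germline(
            config.n_v, config.n_d, config.n_j, config.v_length, seed=s_germ
        )

    truths = []
    if config.inject_targets:
        db, truths = inject_artificial_snps(
            db, list(config.inject_targets), config.n_snps, seed=s_inject
        )
        db, _ = prune_confusable(db, truths)

    # --- usage / junction models --------------------------------------
    if config.usage_tsv:
        usage = UsageModel.from_tsv(config.usage_tsv)
    elif config.target_gene and config.target_usage_pct is not None:
        usage = _usage_with_target(db, config.target_gene, config.target_usage_pct)
    else:
        usage = UsageModel.uniform(db)
    if config.allele_ratio_gene and config.minor_ratio is not None:
        pair = sorted(
            a.name for a in db.by_segment("V") if a.gene == config.allele_ratio_gene
        )
        if len(pair) < 2:
            raise ValueError(
                f"gene {config.allele_ratio_gene} needs two alleles for a ratio"
            )
        usage = UsageModel(
            usage.usage,
            {config.allele_ratio_gene: (pair[0], pair[1], config.minor_ratio)},
        )
    junction = (
        JunctionModel.from_tsv(config.junction_tsv)
        if config.junction_tsv
        else fixtures.default_junction_model()
    )

    # --- rearrangement -------------------------------------------------
    rearrangements = simulate_rearrangements(
        db,
        usage,
        junction,
        config.n_rearrangements,
        config.productive_fraction,
        seed=s_rearr,
    )

    # --- maturation + clonal expansion --------------------------------
    if config.shm and config.iterations > 0:
        from .maturation import MutabilityModel, SubstitutionModel

        mut = (
            MutabilityModel.from_tsv(config.mutability_tsv, config.mut_ability_fold)
            if config.mutability_tsv
            else fixtures.default_mutability_model(
                mut_ability_fold=config.mut_ability_fold
            )
        )
        sub = (
            SubstitutionModel.from_tsv(config.substitution_tsv)
            if config.substitution_tsv
            else fixtures.default_substitution_model()
        )
        lineages = grow_lineages(
            rearrangements,
            config.iterations,
            config.select_fraction,
            mut,
            sub,
            np.random.default_rng(s_mature),
        )
    else:
        lineages = [
            CloneLineage(
                clone_id=f"clone_{r.id}",
                root=r,
                members=[LineageMember(r.sequence, None, 0, 0)],
            )
            for r in rearrangements
        ]
    size_model = ClonalSizeModel(
        alpha=config.alpha,
        max_size=config.max_size,
        max_sequences=config.max_sequences,
    )
    expand_lineages(lineages, size_model, np.random.default_rng(s_expand))

    pool_sequences, pool_weights = [], []
    for lin in lineages:
        for member, size in zip(lin.members, lin.sizes):
            if size > 0:
                pool_sequences.append(member.sequence)
                pool_weights.append(size)

    result = SimulationResult(
        config=config,
        reference=db,
        truths=truths,
        rearrangements=rearrangements,
        lineages=lineages,
        pool_sequences=pool_sequences,
        pool_weights=pool_weights,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .germline import write_germline_fasta, write_truth_tsv
        from .maturation import write_lineage_tsv
        from .rearrange import write_rearrangement_tsv

        write_germline_fasta(db, outdir / f"{config.label}_reference.fasta")
        write_truth_tsv(truths, outdir / f"{config.label}_novel_truth.tsv")
        write_rearrangement_tsv(
            rearrangements, outdir / f"{config.label}_rearrangements.tsv"
        )
        write_lineage_tsv(lineages, outdir / f"{config.label}_lineages.tsv")
        if write_reads:
            profile = ReadProfile(read_length=config.read_length)
            pairs = generate_reads(
                pool_sequences,
                pool_weights,
                profile,
                config.n_reads,
                np.random.default_rng(s_reads),
                id_prefix=config.label,
            )
            write_fastq(
                pairs,
                outdir / f"{config.label}_R1.fastq",
                outdir / f"{config.label}_R2.fastq",
            )
    return result
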