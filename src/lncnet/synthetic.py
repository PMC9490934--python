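"""Synthetic time-course expression data with planted co-expression modules.

The generator emulates a 4-stage (days 0/1/7/14) bulk expression study of
regenerating liver with replicates per stage, a mixture of lncRNA and mRNA
probes, planted co-expression modules whose eigengene trajectories depend
on the stage, background noise genes, a partly module-concordant
protein-interaction graph, and module-enriched gene sets — so that every
downstream stage of the pipeline has ground truth to recover.

Generative model (log2 scale). Gene ``g`` in module ``m`` with membership
strength ``u_g``:

    x_{g,i} = b_g + u_g * e_m(stage(i)) + sqrt(1 - u_g^2) * eps_{g,i}

with baseline ``b_g ~ Normal(8, 1.5)``, noise ``eps ~ Normal(0, noise_sd)``
and ``e_m`` a standardized per-stage trajectory. With ``noise_sd = 1`` the
trajectory and the noise both have unit variance, so ``u_g`` is the
expected correlation between the gene and its module trajectory, and the
expected gene-gene correlation inside a module is ``u_g * u_h``.
Background genes are baseline plus noise only.

Trajectory bank. An unsigned co-expression network (|r|^beta) cannot
separate two modules whose trajectories are near mirror images, so the
default bank for the 4-stage design holds five standardized profiles
numerically optimized to minimize the maximum pairwise |Pearson r|
(0.454, essentially the equiangular-lines bound of 1/sqrt(5) in the
3-dimensional centered stage space) subject to keeping one strongly
day-positive profile (late rise, r = +0.84 with day) and one strongly
day-negative profile (early activation then decline, r = -0.84) — both
signs of module-stage correlation occur, as in real regeneration time
courses. For other stage counts a standardized discrete-cosine basis is
used (cycled if more modules than basis vectors are requested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection, canonical_edges

BACKGROUND = "background"

# Seed-sequence prefixes so each component draws from an independent stream.
_EXPR_STREAM = 11
_PPI_STREAM = 23
_SETS_STREAM = 37

# Standardized per-stage trajectories for the default 4-stage design,
# ordered so module M1 rises late (day r = +0.84) and M2 activates early
# then declines (day r = -0.84).
_TRAJECTORY_BANK_4 = np.array(
    [
        [-0.669, -0.363, -0.685, 1.718],  # late rise
        [0.724, 1.240, -1.053, -0.911],   # early activation, then decline
        [-0.877, 1.492, 0.331, -0.946],   # transient spike at day 1
        [1.729, -0.508, -0.545, -0.676],  # immediate shutdown
        [-0.742, 1.327, -1.163, 0.578],   # rebound
    ]
)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std()


def trajectory_bank(n_stages: int) -> np.ndarray:
    """Standardized stage trajectories available for planting modules."""
    if n_stages == 4:
        return np.array([_standardize(v) for v in _TRAJECTORY_BANK_4])
    if n_stages < 2:
        raise ConfigError("need at least 2 stages")
    j = np.arange(n_stages)
    basis = [
        _standardize(np.cos(np.pi * k * (j + 0.5) / n_stages))
        for k in range(1, n_stages)
    ]
    return np.array(basis)


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults emulate a two-thousand-probe design: 5 planted modules of 60
    genes each on 4 stages x 3 replicates, membership strengths u in
    (0.7, 0.95), the rest background noise.
    """

    n_lncrna: int = 800
    n_mrna: int = 1200
    n_modules: int = 5
    module_sizes: list[int] | None = None
    stages: list[int] = field(default_factory=lambda: [0, 1, 7, 14])
    replicates_per_stage: int = 3
    membership_range: tuple[float, float] = (0.7, 0.95)
    noise_sd: float = 1.0
    background_fraction: float = 0.85
    seed: int = 0

    def resolved_module_sizes(self) -> list[int]:
        if self.module_sizes is not None:
            return list(self.module_sizes)
        total = self.n_lncrna + self.n_mrna
        per = int((1.0 - self.background_fraction) * total) // self.n_modules
        return [per] * self.n_modules

    def validate(self) -> None:
        total = self.n_lncrna + self.n_mrna
        sizes = self.resolved_module_sizes()
        if len(sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes has {len(sizes)} entries for {self.n_modules} modules"
            )
        if sum(sizes) > total:
            raise ConfigError(
                f"module sizes sum to {sum(sizes)} but only {total} genes available"
            )
        if any(s < 1 for s in sizes):
            raise ConfigError("module sizes must be positive")
        low, high = self.membership_range
        if not (0.0 < low < high < 1.0):
            raise ConfigError("membership_range must satisfy 0 < low < high < 1")
        if self.replicates_per_stage < 2:
            raise ConfigError("replicates_per_stage must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction must be in [0, 1]")
        if len(set(self.stages)) < 2:
            raise ConfigError("need at least 2 distinct stages")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure.

    ``module_of`` maps gene id to planted module label ("M1".."Mk") or
    "background"; ``u`` holds membership strengths (0 for background);
    ``trajectories`` is modules x stages (standardized eigengene values).
    """

    module_of: pd.Series
    u: pd.Series
    trajectories: pd.DataFrame
    seed: int

    def members(self, module: str) -> pd.Index:
        return self.module_of.index[self.module_of == module]


@dataclass
class SyntheticDataset:
    expression: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset; bit-identical per seed."""
    config.validate()
    rng = np.random.default_rng([_EXPR_STREAM, config.seed])
    total = config.n_lncrna + config.n_mrna
    sizes = config.resolved_module_sizes()
    stages = list(config.stages)
    n_stages, reps = len(stages), config.replicates_per_stage

    gene_ids = [f"P{i + 1:06d}" for i in range(total)]
    sample_ids = [f"d{d}_r{r + 1}" for d in stages for r in range(reps)]
    stage_idx = np.repeat(np.arange(n_stages), reps)

    # biotype assignment: interleave lncRNA and mRNA proportionally within
    # each module so both biotypes can pass downstream GS/MM filters
    lnc_frac = config.n_lncrna / total
    biotype: list[str] = []
    n_lnc_used = n_mrna_used = 0
    module_labels = [f"M{m + 1}" for m in range(config.n_modules)]
    module_of = []
    for m, size in enumerate(sizes):
        module_of.extend([module_labels[m]] * size)
    module_of.extend([BACKGROUND] * (total - sum(sizes)))
    for g in range(total):
        want_lnc = int(np.floor((g + 1) * lnc_frac)) > int(np.floor(g * lnc_frac))
        if want_lnc and n_lnc_used < config.n_lncrna:
            biotype.append("lncRNA")
            n_lnc_used += 1
        elif n_mrna_used < config.n_mrna:
            biotype.append("mRNA")
            n_mrna_used += 1
        else:
            biotype.append("lncRNA")
            n_lnc_used += 1

    symbols = []
    lnc_i = mrna_i = 0
    for bt in biotype:
        if bt == "lncRNA":
            lnc_i += 1
            symbols.append(f"LNC{lnc_i:05d}")
        else:
            mrna_i += 1
            symbols.append(f"GENE{mrna_i:05d}")

    bank = trajectory_bank(n_stages)
    traj = np.array([bank[m % len(bank)] for m in range(config.n_modules)])
    traj = traj.reshape(config.n_modules, n_stages)
    trajectories = pd.DataFrame(traj, index=module_labels, columns=stages)

    module_of = pd.Series(module_of, index=gene_ids, name="module")
    is_module = (module_of != BACKGROUND).to_numpy()
    low, high = config.membership_range
    u = np.zeros(total)
    u[is_module] = rng.uniform(low, high, size=int(is_module.sum()))

    baseline = rng.normal(8.0, 1.5, size=total)
    eps = rng.normal(0.0, config.noise_sd, size=(total, len(sample_ids)))
    x = baseline[:, None] + eps
    for m, label in enumerate(module_labels):
        rows = (module_of == label).to_numpy()
        e = traj[m][stage_idx]  # per-sample trajectory value
        um = u[rows][:, None]
        x[rows] = (
            baseline[rows][:, None]
            + um * e[None, :]
            + np.sqrt(1.0 - um**2) * eps[rows]
        )

    expression = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    annotation = pd.DataFrame(
        {"symbol": symbols, "biotype": biotype}, index=pd.Index(gene_ids, name="gene_id")
    )
    samples = pd.DataFrame(
        {"day": np.asarray(stages)[stage_idx]}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = SyntheticTruth(
        module_of=module_of,
        u=pd.Series(u, index=gene_ids, name="u"),
        trajectories=trajectories,
        seed=config.seed,
    )
    return SyntheticDataset(expression, annotation, samples, truth, config)


def generate_ppi(
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    within_module_edge_p: float,
    background_edge_p: float,
    seed: int,
) -> pd.DataFrame:
    """Random undirected interaction graph over mRNA symbols.

    Pairs of mRNAs planted in the same module are connected with
    probability ``within_module_edge_p``, all other pairs with
    ``background_edge_p`` — a partly module-concordant stand-in for a
    curated protein-interaction export.
    """
    for name, p in [("within_module_edge_p", within_module_edge_p),
                    ("background_edge_p", background_edge_p)]:
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {p}")
    mrna = annotation.index[annotation["biotype"] == "mRNA"]
    if len(mrna) == 0:
        raise ConfigError("no mRNA genes to build an interaction graph over")
    rng = np.random.default_rng([_PPI_STREAM, seed])
    syms = annotation.loc[mrna, "symbol"].to_numpy()
    mods = truth.module_of.reindex(mrna).to_numpy()
    n = len(mrna)
    ii, jj = np.triu_indices(n, k=1)
    same = (mods[ii] == mods[jj]) & (mods[ii] != BACKGROUND)
    p_edge = np.where(same, within_module_edge_p, background_edge_p)
    keep = rng.random(len(ii)) < p_edge
    return canonical_edges(zip(syms[ii[keep]], syms[jj[keep]]))


def generate_gene_sets(
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    n_sets: int,
    enriched_fraction: float,
    seed: int,
    set_size: int = 30,
) -> GeneSetCollection:
    """GMT-writable gene sets, half module-enriched and half null.

    Even-indexed sets draw ``enriched_fraction`` of their members from one
    planted module (cycling over modules) and the remainder from outside
    it; odd-indexed ("null") sets draw uniformly from all gene symbols.
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ConfigError("enriched_fraction must be in [0, 1]")
    rng = np.random.default_rng([_SETS_STREAM, seed])
    coll = GeneSetCollection()
    if n_sets == 0:
        return coll
    all_syms = annotation["symbol"]
    modules = [m for m in truth.trajectories.index]
    for i in range(n_sets):
        if i % 2 == 0 and enriched_fraction > 0 and modules:
            module = modules[(i // 2) % len(modules)]
            members_in = all_syms.loc[truth.members(module)].to_numpy()
            members_out = all_syms.loc[truth.module_of.index.difference(
                truth.members(module))].to_numpy()
            k_in = min(int(round(enriched_fraction * set_size)), len(members_in))
            k_out = min(set_size - k_in, len(members_out))
            chosen = np.concatenate([
                rng.choice(members_in, size=k_in, replace=False),
                rng.choice(np.sort(members_out), size=k_out, replace=False),
            ])
            coll.add(
                f"enriched_{module}_{i:03d}",
                sorted(chosen),
                description=f"synthetic set enriched for planted module {module}",
            )
        else:
            chosen = rng.choice(np.sort(all_syms.to_numpy()),
                                size=min(set_size, len(all_syms)), replace=False)
            coll.add(f"null_{i:03d}", sorted(chosen),
                     description="synthetic null set drawn uniformly")
    return coll
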