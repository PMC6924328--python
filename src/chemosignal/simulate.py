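"""Synthetic study generator with known ground truth.

Emulates the shape of a host-specificity screening study in
Brassicaceae: 13 test species x 26 glucosinolate compounds x 5
replicate plants x two leaf strata (young leaves roughly twice as
concentrated as old: 33.4 vs 17.8 umol/g totals), a second population
for 6 of the species, sparse (zero-inflated) profile matrices, an
independent "genetic" tree supplying a distance matrix, and feeding
intensity for two insects: a specialist producing overdispersed feeding
-puncture counts and a generalist producing continuous leaf-area
removal (mm^2). The coupling of feeding to chemical-profile distance
vs genetic distance from a reference host is tunable, so parameter
-recovery tests can dial in a pure "chemistry-tracking" or a pure-null
scenario and check what the pipeline reports.

Not emulated: chromatographic raw signal, retention-time drift,
compound identities, or any phylogenetic realism beyond a pure-birth
topology; conclusions about real data rest on the analysis modules, not
on this generator resembling any particular chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import DistanceMatrix, patristic_distances, write_newick

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_tree",
    "simulate_bm_trait",
    "simulate_study",
    "example_compound_flags",
]

_BLOCKS = ("A", "B", "C", "D", "E")

# named rng substreams hanging off the master seed
_SUB_CHEM_TREE = 1
_SUB_GEN_TREE = 2
_SUB_CHEMISTRY = 3
_SUB_FEEDING = 4


def _rng(seed: int | None, substream: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), substream])


def simulate_tree(
    n_tips: int,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
    birth_rate: float = 1.0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree: exponential waiting times, ultrametric tips."""
    if n_tips < 3:
        raise ValueError(f"need n_tips >= 3, got {n_tips}")
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError(f"{len(labels)} labels for {n_tips} tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = dendropy.Node()
    birth_time: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth_time[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    taxa = dendropy.TaxonNamespace(list(labels))
    for label, leaf in zip(labels, active):
        leaf.edge.length = t_end - birth_time[leaf]
        leaf.taxon = taxa.get_taxon(label)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def simulate_bm_trait(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root_state: float = 0.0,
    seed: int | None = None,
) -> pd.Series:
    """Brownian-motion trait: independent normal increments along each edge.

    The increment on an edge of length L has variance ``sigma2 * L``, so
    the tip vector has covariance ``sigma2 * V`` for the tree's VCV.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[node] = float(root_state)
        else:
            length = node.edge.length or 0.0
            values[node] = values[parent] + rng.normal(0.0, np.sqrt(sigma2 * length))
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    trait = pd.Series(out).sort_index()
    trait.index.name = "species"
    return trait


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the screening design."""

    n_species: int = 13
    n_compounds: int = 26
    replicates_per_species: int = 5
    two_population_species: int = 6
    young_total_mean: float = 33.4   # umol/g, mean per-plant total, young leaves
    old_total_mean: float = 17.8     # umol/g, old leaves
    profile_tree_weight: float = 0.8  # tree-structured share of log-profiles
    occupancy: float = 0.35          # P(compound present in a species)
    replicate_cv: float = 0.35       # plant-to-plant lognormal CV
    population_effect_sd: float = 0.2  # log-scale population offset
    chem_signal_weight: float = 1.0  # specialist coupling to chemical distance
    phylo_signal_weight: float = 0.0  # specialist coupling to genetic distance
    bm_rate: float = 1.0             # sigma^2 of the per-compound BM component
    count_max_mean: float = 125.0    # puncture intensity at the reference host
    count_min_mean: float = 0.3      # ... at the most dissimilar species
                                     # (near-zero: complete rejections occur)
    count_dispersion: float = 3.0    # negative-binomial shape (smaller = noisier)
    area_mean: float = 14.0          # mm^2, generalist leaf-area removal
    area_cv: float = 0.45
    generalist_coupling: float = 0.2  # weak dependence of areas on distances
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("chem_signal_weight", "phylo_signal_weight", "profile_tree_weight",
                     "occupancy", "generalist_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 3 or self.n_compounds < 1 or self.replicates_per_species < 2:
            raise ValueError("study too small: need >= 3 species, >= 1 compound, >= 2 replicates")
        if self.two_population_species > self.n_species:
            raise ValueError("two_population_species exceeds n_species")


@dataclass
class StudyData:
    """One synthetic study plus the ground truth that generated it."""

    concentrations: pd.DataFrame
    feeding: pd.DataFrame
    genetic_distances: DistanceMatrix
    chemical_tree: dendropy.Tree
    genetic_tree: dendropy.Tree
    ground_truth: dict

    @property
    def reference_species(self) -> str:
        return self.ground_truth["reference_species"]

    def feeding_for(self, insect: str) -> pd.DataFrame:
        sub = self.feeding[self.feeding["insect"] == insect]
        if sub.empty:
            raise KeyError(
                f"no feeding rows for insect {insect!r}; "
                f"available: {sorted(self.feeding['insect'].unique())}"
            )
        return sub.reset_index(drop=True)

    def write_dir(self, path: str | Path) -> dict[str, Path]:
        """Emit the CSV/newick artefacts the analysis pipeline consumes."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        paths = {
            "concentrations": path / "concentrations.csv",
            "feeding": path / "feeding.csv",
            "genetic_distances": path / "genetic_distances.csv",
            "compound_flags": path / "compound_flags.csv",
            "chemical_tree": path / "chemical_tree_true.nwk",
            "genetic_tree": path / "genetic_tree_true.nwk",
        }
        self.concentrations.to_csv(paths["concentrations"], index=False)
        self.feeding.to_csv(paths["feeding"], index=False)
        self.genetic_distances.to_csv(paths["genetic_distances"])
        flags = pd.DataFrame(
            {
                "compound": sorted(self.concentrations["compound"].unique()),
                "retention_time_min": np.linspace(
                    2.0, 28.0, self.concentrations["compound"].nunique()
                ).round(2),
                "identified_as_gs": True,
                "merge_group": "",
                "notes": "synthetic",
            }
        )
        flags.to_csv(paths["compound_flags"], index=False)
        paths["chemical_tree"].write_text(write_newick(self.chemical_tree) + "\n")
        paths["genetic_tree"].write_text(write_newick(self.genetic_tree) + "\n")
        return paths


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Generate one full synthetic study under ``config``.

    Chemical profiles are a mixture of a Brownian component on a
    "chemical" tree and iid noise on the log scale, masked by a
    per-(species, compound) occupancy draw to mimic sparse GS tables.
    The genetic distance matrix is the patristic matrix of an
    independently simulated tree (additive by construction, so neighbor
    joining reproduces the genetic tree exactly). Specialist feeding
    counts decline from ``count_max_mean`` at the reference species to
    ``count_min_mean`` at the most distant species along a blend of the
    two (normalized) distances weighted by ``chem_signal_weight`` and
    ``phylo_signal_weight``; generalist areas depend only weakly on the
    same blend.
    """
    cfg = config or SimulationConfig()
    species = [f"species_{i + 1:02d}" for i in range(cfg.n_species)]
    compounds = [f"gs{i + 1:02d}" for i in range(cfg.n_compounds)]

    chem_tree = simulate_tree(cfg.n_species, seed=_rng(cfg.seed, _SUB_CHEM_TREE),
                              labels=species)
    gen_tree = simulate_tree(cfg.n_species, seed=_rng(cfg.seed, _SUB_GEN_TREE),
                             labels=species)
    genetic_distances = patristic_distances(gen_tree)

    rng = _rng(cfg.seed, _SUB_CHEMISTRY)
    w = cfg.profile_tree_weight
    logprof = np.empty((cfg.n_species, cfg.n_compounds))
    mask = np.zeros((cfg.n_species, cfg.n_compounds), dtype=bool)
    for c in range(cfg.n_compounds):
        bm = simulate_bm_trait(chem_tree, sigma2=cfg.bm_rate, seed=rng)
        bm = bm.reindex(species).to_numpy()
        bm = (bm - bm.mean()) / max(bm.std(), 1e-12)
        noise = rng.standard_normal(cfg.n_species)
        latent = w * bm + (1.0 - w) * noise
        mu_c = rng.normal(0.0, 1.0)  # compound-level abundance offset
        logprof[:, c] = mu_c + 0.8 * latent
        # clade-structured sparsity: a compound occurs in the species where its
        # latent abundance is highest, so presence/absence (which dominates
        # Euclidean profile distances) tracks the chemical tree the same way
        # the abundances do -- real GS tables show clade-restricted compounds
        n_present = max(1, int(rng.binomial(cfg.n_species, cfg.occupancy)))
        mask[np.argsort(latent)[-n_present:], c] = True
    for i in range(cfg.n_species):  # every species carries at least one compound
        if not mask[i].any():
            mask[i, int(rng.integers(cfg.n_compounds))] = True
    young = np.where(mask, np.exp(logprof), 0.0)
    young *= cfg.young_total_mean / young.sum(axis=1).mean()
    age_jitter = np.exp(rng.normal(0.0, 0.1, size=cfg.n_species))
    old = young * (cfg.old_total_mean / cfg.young_total_mean) * age_jitter[:, None]
    species_means = {"young": young, "old": old}

    sigma_rep = float(np.sqrt(np.log1p(cfg.replicate_cv**2)))
    rows = []
    for i, sp in enumerate(species):
        n_pops = 2 if i < cfg.two_population_species else 1
        for pop in ("A", "B")[:n_pops]:
            pop_shift = (
                np.exp(rng.normal(0.0, cfg.population_effect_sd, size=cfg.n_compounds))
                if pop == "B"
                else np.ones(cfg.n_compounds)
            )
            for age in ("young", "old"):
                base = species_means[age][i] * pop_shift
                for rep in range(1, cfg.replicates_per_species + 1):
                    noise = np.exp(
                        rng.normal(-0.5 * sigma_rep**2, sigma_rep, size=cfg.n_compounds)
                    )
                    conc = base * noise
                    for c, compound in enumerate(compounds):
                        if conc[c] > 0:
                            rows.append((sp, pop, age, rep, compound, conc[c]))
    concentrations = pd.DataFrame(
        rows,
        columns=["species", "population", "leaf_age", "replicate",
                 "compound", "concentration_umol_g"],
    )

    # feeding couples to normalized distances from the reference species
    reference = species[0]
    all_leaf_means = 0.5 * (young + old)
    ref_idx = 0
    d_chem = np.sqrt(((all_leaf_means - all_leaf_means[ref_idx]) ** 2).sum(axis=1))
    d_gen = genetic_distances.to_dataframe().loc[species, reference].to_numpy()
    d_chem_n = d_chem / d_chem.max() if d_chem.max() > 0 else d_chem
    d_gen_n = d_gen / d_gen.max() if d_gen.max() > 0 else d_gen
    total_weight = cfg.chem_signal_weight + cfg.phylo_signal_weight
    if total_weight > 0:
        blend = (cfg.chem_signal_weight * d_chem_n + cfg.phylo_signal_weight * d_gen_n)
        blend = blend / blend.max()
    else:
        blend = np.zeros(cfg.n_species)

    frng = _rng(cfg.seed, _SUB_FEEDING)
    # linear decline from the reference host to the most dissimilar species,
    # matching the linear feeding-vs-distance model of the analysis layer
    lam = cfg.count_max_mean - (cfg.count_max_mean - cfg.count_min_mean) * blend
    area_sigma = float(np.sqrt(np.log1p(cfg.area_cv**2)))
    area_mu = (
        np.log(cfg.area_mean)
        - 0.5 * area_sigma**2
        - cfg.generalist_coupling * (blend - blend.mean())
    )
    k = cfg.count_dispersion
    feeding_rows = []
    for i, sp in enumerate(species):
        for rep in range(1, cfg.replicates_per_species + 1):
            block = _BLOCKS[(rep - 1) % len(_BLOCKS)]
            count = frng.negative_binomial(k, k / (k + lam[i]))
            feeding_rows.append(("specialist", sp, rep, block, float(count)))
        for rep in range(1, cfg.replicates_per_species + 1):
            block = _BLOCKS[(rep - 1) % len(_BLOCKS)]
            area = float(np.exp(frng.normal(area_mu[i], area_sigma)))
            feeding_rows.append(("generalist", sp, rep, block, round(area, 2)))
    feeding = pd.DataFrame(
        feeding_rows, columns=["insect", "species", "replicate", "block", "measure"]
    )

    ground_truth = {
        "config": asdict(cfg),
        "reference_species": reference,
        "species": species,
        "compounds": compounds,
        "species_mean_young": pd.DataFrame(young, index=species, columns=compounds),
        "species_mean_old": pd.DataFrame(old, index=species, columns=compounds),
        "specialist_intensity": pd.Series(lam, index=species),
        "distance_chem_to_ref": pd.Series(d_chem, index=species),
        "distance_genetic_to_ref": pd.Series(d_gen, index=species),
        "chemical_tree_newick": write_newick(chem_tree),
        "genetic_tree_newick": write_newick(gen_tree),
        "signal_expected": total_weight > 0,
    }
    if total_weight == 0:
        import warnings

        ground_truth["warning"] = (
            "both signal weights are 0: feeding is pure noise with respect to both trees"
        )
    return StudyData(
        concentrations=concentrations,
        feeding=feeding,
        genetic_distances=genetic_distances,
        chemical_tree=chem_tree,
        genetic_tree=gen_tree,
        ground_truth=ground_truth,
    )


def example_compound_flags() -> pd.DataFrame:
    """Synthetic 45-peak compound-flag table exercising every reduction rule.

    A stand-in, constructed (not measured) table shaped like a GS screen
    in which 45 chromatographic peaks are flagged so that 11 cannot be
    confirmed as GS, 5 elute after the 30-minute dimer cutoff, and 3
    pairs of near co-eluters are indistinguishable; the reduction rules
    therefore retain 26 compounds.
    """
    n = 45
    ids = [f"peak{i + 1:02d}" for i in range(n)]
    rt = np.round(np.linspace(2.0, 29.0, n - 5), 2).tolist() + [31.2, 33.5, 35.1, 37.8, 39.4]
    identified = [True] * n
    for i in (2, 6, 10, 14, 18, 22, 26, 30, 33, 36, 39):  # 11 unconfirmed peaks
        identified[i] = False
    merge_group = [""] * n
    for g, (a, b) in enumerate([(4, 5), (12, 13), (24, 25)], start=1):
        merge_group[a] = merge_group[b] = f"coelute{g}"
    return pd.DataFrame(
        {
            "compound": ids,
            "retention_time_min": rt,
            "identified_as_gs": identified,
            "merge_group": merge_group,
            "notes": "synthetic",
        }
    )
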