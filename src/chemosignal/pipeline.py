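"""End-to-end analysis: reduce -> aggregate -> trees -> signal -> compare -> regress.

The pipeline consumes the study's file formats (long-format
concentration CSV, compound-flag CSV, feeding CSV, genetic distance CSV
or newick tree), runs every stage for each requested leaf-age stratum,
and emits a machine-readable report mirroring the structure of the
study's summary tables: total-GS ANOVA and population contrasts,
per-species feeding summaries (Kruskal-Wallis for counts, ANOVA for
areas), Blomberg's K with permutation p on each candidate tree, the
bootstrap K comparison between the chemical dendrogram and the genetic
phylogram, the three-predictor multiple regression, and per-compound
Spearman correlations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .profiles import (
    aggregate_profiles,
    apply_compound_reduction,
    read_compound_flags,
    read_concentration_table,
    reduce_compound_list,
    total_gs,
    write_profile_csv,
)
from .phylo_signal import blomberg_k_test, compare_k
from .stats import (
    kruskal_wallis,
    multiple_regression_anova,
    normalized_range,
    one_way_anova,
    population_contrast,
    simple_linreg,
    spearman,
)
from .trees import (
    bootstrap_support,
    distance_to_reference,
    neighbor_joining,
    prune_tips,
    read_distance_csv,
    read_newick_file,
    write_newick,
)

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("chemosignal")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and settings for one full analysis run."""

    concentrations: str | Path
    compound_flags: str | Path
    feeding: str | Path
    genetic: str | Path               # newick (.nwk/.newick/.tre) or distance CSV
    reference_species: str
    leaf_age_modes: tuple[str, ...] = ("young", "old", "all")
    n_perm: int = 999
    compare_iterations: int = 1000
    bootstrap: int = 100
    seed: int = 0
    out_dir: str | Path | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("concentrations", "compound_flags", "feeding", "genetic", "out_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["leaf_age_modes"] = list(self.leaf_age_modes)
        return d


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _is_newick(path: Path) -> bool:
    if path.suffix.lower() in {".nwk", ".newick", ".tre", ".tree"}:
        return True
    head = path.read_text()[:200].lstrip()
    return head.startswith("(")


def _check_labels(conc_species, feeding_species, genetic_labels, reference) -> None:
    """Aggregate every species-label mismatch into a single error."""
    problems = []
    conc_species, genetic_labels = set(conc_species), set(genetic_labels)
    feeding_species = set(feeding_species)
    missing_chem = sorted(feeding_species - conc_species)
    if missing_chem:
        problems.append(f"feeding species absent from concentration table: {missing_chem}")
    missing_gen = sorted(feeding_species - genetic_labels)
    if missing_gen:
        problems.append(f"feeding species absent from genetic input: {missing_gen}")
    chem_not_gen = sorted(conc_species - genetic_labels)
    if chem_not_gen:
        problems.append(f"chemistry species absent from genetic input: {chem_not_gen}")
    for name, pool in (
        ("concentration table", conc_species),
        ("genetic input", genetic_labels),
    ):
        if reference not in pool:
            problems.append(f"reference species {reference!r} absent from {name}")
    if problems:
        raise ValueError("species-label mismatches:\n  " + "\n  ".join(problems))


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute every analysis stage and return the JSON-serializable report.

    Deterministic given ``cfg.seed``: the bootstrap, permutation and
    resampling stages derive their substream seeds from it. If
    ``cfg.out_dir`` is set, the report, trees and profile matrices are
    written there as JSON / newick / CSV.
    """
    table = read_concentration_table(cfg.concentrations)
    table["species"] = table["species"].str.strip()
    feeding = pd.read_csv(cfg.feeding)
    if "insect" not in feeding.columns:
        feeding = feeding.assign(insect="insect_1")
    feeding["species"] = feeding["species"].astype(str).str.strip()
    records = read_compound_flags(cfg.compound_flags)
    log.info("inputs: %d concentration rows, %d feeding rows, %d compound flags",
             len(table), len(feeding), len(records))

    genetic_path = Path(cfg.genetic)
    if _is_newick(genetic_path):
        genetic_tree = read_newick_file(genetic_path)
        genetic_source = "newick"
    else:
        genetic_tree = neighbor_joining(read_distance_csv(genetic_path))
        genetic_source = "distance-matrix (neighbor joining applied)"
    genetic_labels = [leaf.taxon.label.strip() for leaf in genetic_tree.leaf_node_iter()]
    reference = cfg.reference_species.strip()
    _check_labels(table["species"], feeding["species"], genetic_labels, reference)

    retained, merges = reduce_compound_list(records)
    reduced = apply_compound_reduction(table, retained, merges)
    dropped = table["compound"].nunique() - reduced["compound"].nunique() + (
        sum(len(m) for m in merges.values()) - len(merges)
    )
    log.info("compound reduction: %d detected -> %d retained (%d merged groups)",
             len(records), len(retained), len(merges))

    # species-level profile matrices and dendrograms per leaf-age mode
    profiles: dict[str, pd.DataFrame] = {}
    dendrograms: dict[str, object] = {}
    rng = np.random.default_rng([cfg.seed, 101])
    for mode in cfg.leaf_age_modes:
        matrix = aggregate_profiles(reduced, retained, leaf_age_mode=mode)
        profiles[mode] = matrix
        dendrograms[mode] = bootstrap_support(
            matrix, b=cfg.bootstrap, seed=int(rng.integers(2**31))
        )
        log.info("dendrogram (%s leaves): %d species, %d compounds, %d bootstrap reps",
                 mode, *matrix.shape, cfg.bootstrap)

    # total GS: per-plant totals, species ANOVA, population contrasts
    plant_totals = total_gs(reduced).reset_index()
    by_species = {
        sp: sub["total_gs_umol_g"].to_numpy()
        for sp, sub in plant_totals.groupby("species", sort=False)
    }
    totals_anova = one_way_anova(by_species)
    contrasts = {}
    for sp, sub in plant_totals.groupby("species", sort=False):
        if sub["population"].nunique() == 2:
            contrasts[sp] = population_contrast(plant_totals, sp)
    totals_mode = "all" if "all" in profiles else cfg.leaf_age_modes[-1]
    species_totals = profiles[totals_mode].sum(axis=1)

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": cfg.as_dict(),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "genetic_input": genetic_source,
        },
        "compounds": {
            "n_detected": len(records),
            "n_retained": len(retained),
            "n_discarded": dropped,
            "retained": retained,
            "merges": merges,
        },
        "total_gs": {
            "anova": totals_anova,
            "population_contrasts": contrasts,
            "species_means": species_totals.round(6).to_dict(),
        },
        "trees": {"genetic": write_newick(genetic_tree)},
        "insects": {},
    }
    for mode, tree in dendrograms.items():
        report["trees"][f"chemical_{mode}"] = write_newick(tree)

    crng = np.random.default_rng([cfg.seed, 202])
    for insect, frame in feeding.groupby("insect", sort=False):
        species_present = sorted(frame["species"].unique())
        means = frame.groupby("species", sort=False)["measure"].mean()
        log.info("insect %s: %d species with feeding data", insect, len(species_present))

        gen_pruned = prune_tips(genetic_tree, species_present)
        entry: dict = {
            "species_means": means.round(6).to_dict(),
            "n_species": len(species_present),
            "kruskal_wallis": kruskal_wallis(
                {sp: sub["measure"].to_numpy() for sp, sub in frame.groupby("species")}
            ),
            "normalized_range": normalized_range(means.to_numpy()),
            "signal": {},
            "compare": {},
        }
        try:
            entry["anova"] = one_way_anova(
                {sp: sub["measure"].to_numpy() for sp, sub in frame.groupby("species")}
            )
        except ValueError as exc:
            entry["anova"] = {"error": str(exc)}

        res = blomberg_k_test(
            gen_pruned, means, n_perm=cfg.n_perm,
            seed=int(crng.integers(2**31)),
            tree_id="genetic", trait_id=str(insect),
        )
        entry["signal"]["genetic"] = res.as_dict()
        for mode, tree in dendrograms.items():
            chem_pruned = prune_tips(tree, species_present)
            res = blomberg_k_test(
                chem_pruned, means, n_perm=cfg.n_perm,
                seed=int(crng.integers(2**31)),
                tree_id=f"chemical_{mode}", trait_id=str(insect),
            )
            entry["signal"][f"chemical_{mode}"] = res.as_dict()
            comparison = compare_k(
                chem_pruned, gen_pruned,
                frame.rename(columns={"measure": "measure"}),
                b=cfg.compare_iterations,
                seed=int(crng.integers(2**31)),
            )
            entry["compare"][f"chemical_{mode}_vs_genetic"] = comparison.as_dict()

        # regression layer: feeding ~ genetic distance + chemical distance + total GS
        # (patristic distances to the reference tip on the full, unpruned trees)
        mode_all = "all" if "all" in dendrograms else cfg.leaf_age_modes[-1]
        d_gen_ref = distance_to_reference(genetic_tree, reference)
        d_chem_ref = distance_to_reference(dendrograms[mode_all], reference)
        rows = sorted(species_present)
        predictors = pd.DataFrame(
            {
                "phylogenetic_distance": [
                    0.0 if s == reference else d_gen_ref[s] for s in rows
                ],
                "gs_profile_distance": [
                    0.0 if s == reference else d_chem_ref[s] for s in rows
                ],
                "total_gs": [species_totals[s] for s in rows],
            },
            index=rows,
        )
        y = means.reindex(predictors.index)
        effects = multiple_regression_anova(y, predictors)
        entry["regression"] = {
            "effects": effects.reset_index().to_dict(orient="records"),
            "r_squared": effects.attrs["r_squared"],
            "n": effects.attrs["n"],
            "simple": {
                name: simple_linreg(predictors[name], y) for name in predictors.columns
            },
        }

        profile_all = profiles[mode_all].reindex(predictors.index)
        spearman_rows = {}
        for compound in profile_all.columns:
            conc = profile_all[compound]
            if conc.nunique() <= 1:
                continue  # compound absent (or constant) across these species
            rho, p = spearman(conc.to_numpy(), y.to_numpy())
            spearman_rows[compound] = {"rho": rho, "p": p}
        entry["spearman"] = spearman_rows
        report["insects"][str(insect)] = entry

    if cfg.out_dir is not None:
        _write_outputs(report, profiles, cfg)
    return report


def _write_outputs(report: dict, profiles: dict, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    for name, newick in report["trees"].items():
        (out / f"tree_{name}.nwk").write_text(newick + "\n")
    for mode, matrix in profiles.items():
        write_profile_csv(matrix, out / f"profiles_{mode}.csv")
    for insect, entry in report["insects"].items():
        safe = str(insect).replace(" ", "_")
        pd.DataFrame(entry["regression"]["effects"]).to_csv(
            out / f"regression_{safe}.tsv", sep="\t", index=False
        )
    log.info("wrote report and tables to %s", out)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
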