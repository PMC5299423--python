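"""End-to-end orchestration: filters -> habitats -> associations ->
niches -> signal statistics -> dispersion, under one seeded config."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateInputError, PipelineError, ValidationError
from .habitat import HabitatMap, classify_habitats, torus_translation_tests, write_habitat_map
from .io_formats import (
    PhylogeneticTree,
    StemMap,
    read_newick_file,
    read_plot_tables,
    write_environment_table,
    write_newick_file,
    write_stem_table,
)
from .niche import DEFAULT_AXES, niche_table, soil_pca
from .phylosignal import (
    KCalculator,
    k_permutation_test,
    sankoff_permutation_test,
    ses_dispersion,
)
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger("nichesignal")

STAGE_DEFAULT_MIN = {"seedling": 20, "adult": 100}


@dataclass(frozen=True)
class StageFilter:
    """Abundance filter for one life stage."""

    stage: str
    min_abundance: int | None = None
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGE_DEFAULT_MIN:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.min_abundance is not None and self.min_abundance < 1:
            raise ValidationError("min_abundance must be >= 1")

    @property
    def threshold(self) -> int:
        if self.min_abundance is None:
            return STAGE_DEFAULT_MIN[self.stage]
        return self.min_abundance


def filter_species(
    stem_map: StemMap,
    stage_filter: StageFilter,
    tree: PhylogeneticTree | None = None,
) -> list[str]:
    """Species of the stage with abundance >= threshold, on the tree,
    minus explicit exclusions; sorted and deduplicated."""
    counts = stem_map.abundance(stage=stage_filter.stage)
    kept = sorted(counts.index[counts >= stage_filter.threshold])
    kept = [sp for sp in kept if sp not in set(stage_filter.exclude)]
    if tree is not None:
        on_tree = set(tree.tip_labels)
        dropped = [sp for sp in kept if sp not in on_tree]
        if dropped:
            logger.warning(
                "dropping %d species absent from the tree: %s",
                len(dropped), dropped[:5],
            )
        kept = [sp for sp in kept if sp in on_tree]
    if not kept:
        raise ValidationError(
            f"no species pass the {stage_filter.stage} filter "
            f"(threshold {stage_filter.threshold})"
        )
    return kept


def assign_preference_groups(
    associations: pd.DataFrame,
) -> tuple[dict[str, str], set[str]]:
    """Species -> habitat-preference group, plus the removed set.

    Positive for exactly one habitat -> that habitat's group; no
    positive and no negative verdicts -> neutral; any negative verdict
    or positive for two or more habitats -> removed.
    """
    required = {"species", "habitat", "verdict"}
    if not required <= set(associations.columns):
        raise ValidationError(
            f"association table needs columns {sorted(required)}"
        )
    habitats = sorted(associations["habitat"].unique())
    groups: dict[str, str] = {}
    removed: set[str] = set()
    for sp, sub in associations.groupby("species"):
        if sorted(sub["habitat"]) != habitats:
            raise ValidationError(f"missing verdicts for species {sp!r}")
        pos = sub.loc[sub["verdict"] == "positive", "habitat"].tolist()
        neg = sub.loc[sub["verdict"] == "negative", "habitat"].tolist()
        if neg or len(pos) > 1:
            removed.add(sp)
        elif len(pos) == 1:
            groups[sp] = pos[0]
        else:
            groups[sp] = "neutral"
    return groups, removed


@dataclass
class PipelineConfig:
    """Flat configuration for a full run (file-backed or simulated)."""

    simulate: bool = True
    tree_path: str | None = None
    stem_path: str | None = None
    env_path: str | None = None
    quadrat_size: float = 20.0
    n_habitats: int = 3
    alpha: float = 0.025
    include_reflections: bool = True
    n_soil_axes: int = 3
    n_bins: int = 20
    min_bin_quadrats: int = 5
    n_perm: int = 999
    n_null: int = 999
    seedling_min: int = 20
    adult_min: int = 100
    exclude: tuple[str, ...] = ()
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key-value file (``key: value`` per line).

        Keys prefixed ``sim_`` configure the synthetic generator.
        """
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must be flat key: value lines")
        sim_kwargs = {
            k[4:]: v for k, v in raw.items() if k.startswith("sim_")
        }
        kwargs = {k: v for k, v in raw.items() if not k.startswith("sim_")}
        if "exclude" in kwargs and isinstance(kwargs["exclude"], str):
            kwargs["exclude"] = tuple(
                s.strip() for s in kwargs["exclude"].split(",") if s.strip()
            )
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs, sim=SimulationConfig(**sim_kwargs))
        return cfg

    def to_flat_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "sim"
        }
        for k, v in dataclasses.asdict(self.sim).items():
            d[f"sim_{k}"] = v
        return d


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage_analysis(
    stage: str,
    threshold: int,
    tree: PhylogeneticTree,
    stems: StemMap,
    grid,
    hmap: HabitatMap,
    config: PipelineConfig,
    seeds: dict[str, int],
) -> dict:
    """All per-stage tables; raises PipelineError naming the stage."""
    try:
        species = filter_species(
            stems, StageFilter(stage, threshold, config.exclude), tree
        )
    except ValidationError as exc:
        raise PipelineError(f"stage {stage}: species filter: {exc}") from exc
    logger.info("%s: %d species pass the filter", stage, len(species))

    assoc = torus_translation_tests(
        stems, hmap, species, alpha=config.alpha,
        include_reflections=config.include_reflections, stage=stage,
    )
    groups, removed = assign_preference_groups(assoc)

    niches = niche_table(
        stems, grid, species, axes=DEFAULT_AXES,
        n_bins=config.n_bins, min_bin_quadrats=config.min_bin_quadrats,
        stage=stage,
    )

    sub = tree.subtree(species)
    calc = KCalculator(sub)
    k_rows = []
    for i, axis in enumerate(DEFAULT_AXES):
        trait = niches.loc[niches["axis"] == axis].set_index("species")[
            "niche_value"
        ]
        try:
            res = k_permutation_test(
                sub, trait, n_perm=config.n_perm,
                seed=seeds["k"] + i, calculator=calc,
            )
        except DegenerateInputError as exc:
            raise PipelineError(
                f"stage {stage}, axis {axis}: {exc}"
            ) from exc
        k_rows.append(
            {"stage": stage, "axis": axis, "n_species": len(species),
             "K": res.observed, "p": res.p_value}
        )
    k_table = pd.DataFrame(k_rows)

    retained = sorted(set(species) - removed)
    states = {sp: groups[sp] for sp in retained}
    if len(retained) >= 2:
        sank_tree = tree.subtree(retained)
        sank = sankoff_permutation_test(
            sank_tree, states, n_perm=config.n_perm, seed=seeds["sankoff"]
        )
        sankoff_table = pd.DataFrame(
            [{"stage": stage, "n_species": len(retained),
              "sankoff_score": sank.observed, "p": sank.p_value}]
        )
    else:
        logger.warning(
            "stage %s: only %d species retained after the removal rule; "
            "skipping the parsimony test", stage, len(retained),
        )
        sankoff_table = pd.DataFrame(
            columns=["stage", "n_species", "sankoff_score", "p"]
        )

    disp_rows = []
    group_labels = list(hmap.names) + ["neutral"]
    disp_tree = tree.subtree(retained) if len(retained) >= 2 else None
    for j, glab in enumerate(group_labels):
        members = sorted(sp for sp, g in states.items() if g == glab)
        row = {"stage": stage, "group": glab, "n_species": len(members)}
        if disp_tree is not None and 2 <= len(members) < len(retained):
            try:
                res = ses_dispersion(
                    disp_tree, members, retained,
                    n_null=config.n_null, seed=seeds["dispersion"] + j,
                    group_label=glab,
                )
                row.update(
                    NRI=res.nri, p_NRI=res.p_mpd,
                    NTI=res.nti, p_NTI=res.p_mntd,
                )
            except DegenerateInputError as exc:
                logger.warning("stage %s group %s: %s", stage, glab, exc)
        disp_rows.append(row)
    dispersion_table = pd.DataFrame(disp_rows)

    group_table = pd.DataFrame(
        [{"species": sp, "stage": stage,
          "group": groups.get(sp, "removed")} for sp in species]
    )
    return {
        "species": species,
        "retained": retained,
        "associations": assoc,
        "groups": group_table,
        "niches": niches,
        "k_table": k_table,
        "sankoff_table": sankoff_table,
        "dispersion_table": dispersion_table,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write all result tables + manifest.

    Returns a dict of the in-memory tables keyed by output name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(8)
    seeds = {
        name: int(child.generate_state(1)[0]) % (2**31)
        for name, child in zip(
            ["sim", "classify", "k_seedling", "k_adult",
             "sankoff_seedling", "sankoff_adult",
             "disp_seedling", "disp_adult"],
            children,
        )
    }

    if config.simulate:
        ds = simulate_dataset(config.sim.with_seed(seeds["sim"]))
        tree, stems, grid = ds.tree, ds.stems, ds.grid
        write_newick_file(tree, out / "tree.nwk")
        write_stem_table(stems, out / "stems.tsv")
        ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                        float_format="%.10g")
    else:
        if not (config.tree_path and config.stem_path and config.env_path):
            raise ValidationError(
                "file-backed run needs tree_path, stem_path and env_path"
            )
        tree = read_newick_file(config.tree_path)
        stems, grid = read_plot_tables(
            config.stem_path, config.env_path, config.quadrat_size
        )

    pca = soil_pca(grid, config.n_soil_axes)
    write_environment_table(grid, out / "environment.tsv")
    hmap = classify_habitats(grid, config.n_habitats, seed=seeds["classify"])
    write_habitat_map(hmap, out / "habitat_map.csv")

    results: dict = {}
    thresholds = {"seedling": config.seedling_min, "adult": config.adult_min}
    per_stage = {}
    for stage in ("seedling", "adult"):
        per_stage[stage] = _stage_analysis(
            stage, thresholds[stage], tree, stems, grid, hmap, config,
            seeds={"k": seeds[f"k_{stage}"],
                   "sankoff": seeds[f"sankoff_{stage}"],
                   "dispersion": seeds[f"disp_{stage}"]},
        )

    for stage, res in per_stage.items():
        for name in ("associations", "groups", "niches", "k_table",
                     "sankoff_table", "dispersion_table"):
            key = f"{name}_{stage}"
            results[key] = res[name]
            _write_table(res[name], out / f"{key}.tsv")

    # cross-stage: K on the intersection of the two stage species lists
    common = sorted(
        set(per_stage["seedling"]["species"])
        & set(per_stage["adult"]["species"])
    )
    cross_rows = []
    if len(common) >= 3:
        cross_tree = tree.subtree(common)
        cross_calc = KCalculator(cross_tree)
        for stage, res in per_stage.items():
            niches = res["niches"]
            for i, axis in enumerate(DEFAULT_AXES):
                trait = (
                    niches.loc[niches["axis"] == axis]
                    .set_index("species")["niche_value"]
                    .reindex(common)
                )
                r = k_permutation_test(
                    cross_tree, trait, n_perm=config.n_perm,
                    seed=seeds[f"k_{stage}"] + 100 + i,
                    calculator=cross_calc,
                )
                cross_rows.append(
                    {"stage": stage, "axis": axis, "n_species": len(common),
                     "K": r.observed, "p": r.p_value}
                )
    cross = pd.DataFrame(cross_rows)
    results["k_table_cross_stage"] = cross
    _write_table(cross, out / "k_table_cross_stage.tsv")

    manifest = {
        "version": __version__,
        "config": config.to_flat_dict(),
        "seeds": seeds,
        "soil_pca_explained": [float(v) for v in pca.explained],
        "habitat_quadrats": {
            name: int(c) for name, c in hmap.quadrat_counts().items()
        },
        "species_counts": {
            stage: {
                "filtered": len(res["species"]),
                "retained": len(res["retained"]),
            }
            for stage, res in per_stage.items()
        },
        "n_common_species": len(common),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    manifest["outputs"].append("manifest.json")
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
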