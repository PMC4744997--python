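"""End-to-end orchestration of the continuous and discrete schemes.

The in-memory entry points :func:`continuous_scheme` and
:func:`discrete_scheme` run the full method on an
:class:`~nichescheme.trait_data.Assemblage`; :func:`run_continuous` and
:func:`run_discrete` add file I/O around them, driven by a flat
YAML/JSON config, and write deterministic CSV/JSON/newick artifacts
plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nichescheme._version import __version__ as _pkg_version
from nichescheme.cart import GrowthParams, assign_groups, cv_prune_1se, grow_tree
from nichescheme.classification import (
    DEFAULT_HIERARCHY,
    assign_niche_codes,
    build_composite_tree,
    composite_outline,
    composite_to_newick,
    occupancy,
)
from nichescheme.evaluation import correlate_axes
from nichescheme.ordination import meta_ordinate, ordinate_dimension, pca_correlation
from nichescheme.phylospace import parse_newick, project_phylogeny
from nichescheme.trait_data import (
    Assemblage,
    load_abundance_table,
    load_trait_table,
    standardize,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    traits: dict                      # dimension label -> path
    abundance: str | None = None
    newick: str | None = None
    hierarchy_order: tuple | None = None
    retained: int = 2
    growth: GrowthParams = field(default_factory=GrowthParams)
    seed: int = 0
    outdir: str = "nichescheme_out"

    def __post_init__(self):
        if len(self.traits) < 2:
            raise PipelineError("config must list >= 2 trait dimensions")
        for dim, path in self.traits.items():
            if not Path(path).exists():
                raise PipelineError(f"trait table for {dim!r} not found: {path}")
        for path in (self.abundance, self.newick):
            if path and not Path(path).exists():
                raise PipelineError(f"input not found: {path}")
        self.growth.seed = self.seed

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        growth_fields = {
            k: data.pop(k)
            for k in ("minsplit", "minbucket", "cp_min", "max_depth", "cv_folds")
            if k in data
        }
        if "hierarchy_order" in data and data["hierarchy_order"] is not None:
            data["hierarchy_order"] = tuple(data["hierarchy_order"])
        cfg = cls(growth=GrowthParams(**growth_fields), **data)
        return cfg

    def manifest(self) -> dict:
        payload = {
            "traits": dict(self.traits),
            "abundance": self.abundance,
            "newick": self.newick,
            "hierarchy_order": list(self.hierarchy_order) if self.hierarchy_order else None,
            "retained": self.retained,
            "growth": asdict(self.growth),
            "seed": self.seed,
            "version": _pkg_version,
        }
        blob = json.dumps(payload, sort_keys=True)
        payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return payload


def load_assemblage(cfg: RunConfig) -> Assemblage:
    tables = [load_trait_table(path, dim) for dim, path in cfg.traits.items()]
    return Assemblage(tuple(tables))


# ---------------------------------------------------------------- continuous


def continuous_scheme(assemblage: Assemblage, response=None, phylo=None,
                      retained: int = 2):
    """Per-dimension PCAs, the meta-ordination, and optional evaluation.

    Returns a dict with keys ``dimension_ordinations``, ``meta``,
    ``raw`` (pooled 38-trait-style baseline PCA), and, when inputs are
    supplied, ``correlations`` and ``projection``.
    """
    ords = [ordinate_dimension(tm, retained) for tm in assemblage.dimension_tables]
    meta = meta_ordinate(ords)
    pooled = standardize(assemblage.pooled())
    raw = pca_correlation(pooled.values, pooled.trait_names)
    out = {"dimension_ordinations": ords, "meta": meta, "raw": raw}
    if response is not None:
        resp = response.reorder(assemblage.species_ids)
        out["correlations"] = correlate_axes(
            meta, ords, (raw.scores, assemblage.species_ids), resp
        )
    if phylo is not None:
        out["projection"] = project_phylogeny(
            phylo, meta.species_ids, meta.pca.scores
        )
    return out


def run_continuous(cfg: RunConfig):
    """File-driven continuous-scheme run; writes CSV/newick artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assemblage = load_assemblage(cfg)
    response = load_abundance_table(cfg.abundance) if cfg.abundance else None
    phylo = None
    if cfg.newick:
        phylo = parse_newick(
            Path(cfg.newick).read_text(),
            assemblage_species=assemblage.species_ids,
            prune=True,
        )
    try:
        result = continuous_scheme(assemblage, response, phylo, cfg.retained)
    except Exception as exc:
        raise PipelineError(f"continuous scheme failed: {exc}") from exc

    species = list(assemblage.species_ids)
    for o in result["dimension_ordinations"]:
        df = pd.DataFrame(
            o.retained_scores,
            index=species,
            columns=[f"PC{k + 1}" for k in range(o.retained)],
        )
        df.index.name = "species_id"
        df.to_csv(outdir / f"scores_{o.dimension}.csv", float_format="%.10g")
    meta_df = pd.DataFrame(
        result["meta"].pca.scores[:, : cfg.retained],
        index=species,
        columns=[f"metaPC{k + 1}" for k in range(cfg.retained)],
    )
    meta_df.index.name = "species_id"
    meta_df.to_csv(outdir / "scores_meta.csv", float_format="%.10g")
    prop = {
        o.dimension: [float(v) for v in o.pca.prop_var[: o.retained]]
        for o in result["dimension_ordinations"]
    }
    prop["meta"] = [float(v) for v in result["meta"].pca.prop_var[: cfg.retained]]
    (outdir / "prop_var.json").write_text(json.dumps(prop, indent=2, sort_keys=True))
    if "correlations" in result:
        result["correlations"].to_csv(outdir / "correlations.csv")
    if "projection" in result:
        (outdir / "projection.nwk").write_text(result["projection"].to_newick() + "\n")
        node_df = pd.DataFrame(
            result["projection"].node_scores, columns=["metaPC1", "metaPC2"]
        )
        node_df.index.name = "node"
        node_df.to_csv(outdir / "projection_nodes.csv", float_format="%.10g")
    _write_manifest(cfg, outdir)
    return result


# ------------------------------------------------------------------ discrete


def discrete_scheme(assemblage: Assemblage, params: GrowthParams | None = None,
                    hierarchy_order=None, retained: int = 2):
    """Per-dimension regression trees, pruning, niche codes, occupancy.

    Returns a dict with ``trees`` (pruned per dimension), ``groups``,
    ``classification`` and ``composite`` (nested dendrogram).
    """
    if params is None:
        params = GrowthParams()
    if hierarchy_order is None:
        hierarchy_order = tuple(
            d for d in DEFAULT_HIERARCHY if d in assemblage.dimensions
        ) + tuple(d for d in assemblage.dimensions if d not in DEFAULT_HIERARCHY)
    species = assemblage.species_ids
    trees = {}
    groups = {}
    for dim in hierarchy_order:
        tm = assemblage[dim]
        ordn = ordinate_dimension(tm, retained)
        full = grow_tree(tm.values, ordn.retained_scores, params, tm.trait_names)
        pruned = cv_prune_1se(full, tm.values, ordn.retained_scores, params)
        trees[dim] = pruned
        labels = assign_groups(pruned, tm.values, tm.trait_names)
        groups[dim] = {sp: int(g) for sp, g in zip(species, labels)}
    codes = assign_niche_codes(groups, hierarchy_order)
    leaf_counts = tuple(trees[d].n_leaves for d in hierarchy_order)
    classification = occupancy(codes, leaf_counts, hierarchy_order, groups)
    composite = build_composite_tree(
        leaf_counts, hierarchy_order, classification.occupied
    )
    return {
        "trees": trees,
        "groups": groups,
        "classification": classification,
        "composite": composite,
    }


def run_discrete(cfg: RunConfig):
    """File-driven discrete-scheme run; writes codes, occupancy, trees."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assemblage = load_assemblage(cfg)
    try:
        result = discrete_scheme(
            assemblage, cfg.growth, cfg.hierarchy_order, cfg.retained
        )
    except Exception as exc:
        raise PipelineError(f"discrete scheme failed: {exc}") from exc

    cls = result["classification"]
    codes_df = pd.DataFrame(
        {
            "species_id": sorted(cls.codes),
            "niche_code": [
                ",".join(map(str, cls.codes[sp])) for sp in sorted(cls.codes)
            ],
        }
    )
    codes_df.to_csv(outdir / "niche_codes.csv", index=False)
    (outdir / "occupancy.json").write_text(cls.to_json())
    cp_tables = {
        dim: [list(row) for row in tree.cp_table]
        for dim, tree in result["trees"].items()
    }
    (outdir / "cp_tables.json").write_text(
        json.dumps(cp_tables, indent=2, sort_keys=True)
    )
    outlines = "\n\n".join(
        f"== {dim} ({tree.n_leaves} groups) ==\n{tree.outline()}"
        for dim, tree in result["trees"].items()
    )
    (outdir / "trees.txt").write_text(outlines + "\n")
    (outdir / "composite.nwk").write_text(
        composite_to_newick(result["composite"], cls.hierarchy_order) + "\n"
    )
    (outdir / "composite_outline.txt").write_text(
        composite_outline(result["composite"], cls.hierarchy_order) + "\n"
    )
    _write_manifest(cfg, outdir)
    return result


def _write_manifest(cfg: RunConfig, outdir: Path) -> None:
    manifest = cfg.manifest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    print(
        f"[nichescheme] wrote {outdir} (seed={cfg.seed}, "
        f"config {manifest['config_hash']})",
        file=sys.stderr,
    )
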