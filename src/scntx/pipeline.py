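"""End-to-end orchestration: simulate/load -> filter -> collapse -> map ->
differential expression -> meta-analysis -> stability -> enrichment -> EWCE
-> reports, with a JSON run manifest.

Reruns with an identical config and seed are byte-identical: all randomness
derives from the config seed via fixed stream indices, and no output embeds
timestamps.  Logging goes to stderr, never into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import collapse as _collapse
from . import diffexpr as _de
from . import enrichment as _enr
from . import ewce as _ewce
from . import report as _report
from .io import (
    read_donor_bundle,
    read_gene_sets_gmt,
    read_gene_disease_table,
    read_homology_table,
    read_network_masks,
)
from .mapping import assign_samples, tabulate_assignments
from .synthetic import (
    SyntheticConfig,
    config_from_dict,
    generate_atlas,
    generate_dataset,
    generate_gene_sets,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "save_gene_matrices", "load_gene_matrices"]

DEFAULT_TARGETS = {
    "C": ["A", "B", "E", "F", "G", "H", "I"],
    "D": ["A", "B", "E", "F", "G", "H", "I"],
}


@dataclass
class RunConfig:
    """One run's inputs, thresholds and seeds."""

    out_dir: str = "scn_run"
    seed: int = 0
    simulate: SyntheticConfig | None = None
    inputs: dict | None = None  # file mode: bundle manifest + resource paths
    targets: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TARGETS.items()})
    pa_fraction: float = 0.01
    fc_thresh: float = 1.0
    alpha: float = 0.05
    pathway_min_set: int = 10
    marker_min_set: int = 6
    disease_min_set: int = 1
    summary_test: str = "z"
    ewce_reps: int = 10000
    overlap_policy: str = "first"
    enrich_direction: str = "up"

    def __post_init__(self) -> None:
        for target, comparison in self.targets.items():
            if target in comparison:
                raise ValueError(f"target {target!r} appears in its own comparison list")
            if not comparison:
                raise ValueError(f"empty comparison list for target {target!r}")
        for name in ("pa_fraction", "fc_thresh", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrich_direction not in ("up", "down", "all"):
            raise ValueError("enrich_direction must be up, down or all")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a simulate block or an inputs block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if raw.get("simulate") is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = config_from_dict(sim)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            from .synthetic import _config_to_jsonable

            d["simulate"] = _config_to_jsonable(self.simulate)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_gene_matrices(gms: Sequence[_collapse.GeneMatrix], out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chosen = pd.DataFrame(
        sorted(gms[0].chosen_probe.items()), columns=["entrez_id", "probe_id"]
    )
    chosen.to_csv(out_dir / "chosen_probes.tsv", sep="\t", index=False)
    entries = []
    for gm in gms:
        ddir = out_dir / gm.donor_id
        ddir.mkdir(exist_ok=True)
        gm.expr.rename_axis("entrez_id").to_csv(ddir / "gene_expression.tsv", sep="\t")
        samples = gm.samples.copy()
        samples.insert(0, "donor_id", gm.donor_id)
        samples.rename_axis("sample_id").to_csv(ddir / "samples.tsv", sep="\t")
        entries.append({"donor_id": gm.donor_id, "dir": str(ddir)})
    return {"chosen_probes": str(out_dir / "chosen_probes.tsv"), "donors": entries}


def load_gene_matrices(out_dir) -> list[_collapse.GeneMatrix]:
    out_dir = Path(out_dir)
    chosen = pd.read_csv(out_dir / "chosen_probes.tsv", sep="\t")
    chosen_map = dict(zip(chosen["entrez_id"].astype(int), chosen["probe_id"].astype(str)))
    gms = []
    for ddir in sorted(p for p in out_dir.iterdir() if p.is_dir()):
        expr = pd.read_csv(ddir / "gene_expression.tsv", sep="\t", index_col=0)
        expr.index = expr.index.astype(int)
        samples = pd.read_csv(ddir / "samples.tsv", sep="\t", dtype={"sample_id": str}).set_index(
            "sample_id"
        )
        donor_id = str(samples["donor_id"].iloc[0])
        gms.append(
            _collapse.GeneMatrix(
                donor_id=donor_id,
                expr=expr,
                samples=samples.drop(columns=["donor_id"]),
                chosen_probe=chosen_map,
            )
        )
    return gms


def load_bundle_manifest(path) -> list:
    """Load donor bundles from a YAML manifest with a ``donors`` list."""
    manifest = yaml.safe_load(Path(path).read_text())
    bundles = []
    for entry in manifest["donors"]:
        bundles.append(
            read_donor_bundle(entry["expr"], entry["pa"], entry["probes"], entry["samples"])
        )
    return bundles


def _load_file_inputs(inputs: Mapping):
    bundles = load_bundle_manifest(inputs["bundle_manifest"])
    atlas = None
    if "mask_paths" in inputs:
        atlas = read_network_masks(inputs["mask_paths"], inputs["mask_labels"])
    return bundles, atlas


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write artifacts plus a run manifest.

    Returns the manifest dict (also written to ``<out_dir>/run_manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    resources = None
    truth = None

    def _stage(name):
        logger.info("stage: %s", name)

    if cfg.simulate is not None:
        _stage("simulate")
        atlas = generate_atlas(cfg.simulate)
        bundles, truth = generate_dataset(cfg.simulate, atlas)
        resources = generate_gene_sets(truth, cfg.simulate)
    else:
        _stage("load")
        bundles, atlas = _load_file_inputs(cfg.inputs)
        if atlas is None:
            raise ValueError("file-mode runs require mask_paths/mask_labels")

    _stage("filter+collapse")
    filtered = _collapse.filter_probes(bundles, pa_fraction=cfg.pa_fraction)
    gms = _collapse.collapse_probes(filtered)
    universe = frozenset(int(g) for g in gms[0].genes)
    written["collapsed"] = Path(save_gene_matrices(gms, out / "collapsed")["chosen_probes"])

    _stage("map")
    assignment = assign_samples(atlas, bundles, overlap_policy=cfg.overlap_policy)
    assignment.to_csv(out / "assignments.tsv", sep="\t", index=False)
    written["assignments"] = out / "assignments.tsv"
    counts = tabulate_assignments(assignment, labels=atlas.labels)
    counts.to_csv(out / "sample_counts.tsv", sep="\t")
    written["sample_counts"] = out / "sample_counts.tsv"

    # file-mode resources are read against the post-collapse universe
    if cfg.simulate is None and cfg.inputs:
        res_paths = cfg.inputs
        pathways = (
            read_gene_sets_gmt(res_paths["pathways"], universe)
            if "pathways" in res_paths else None
        )
        diseases = (
            read_gene_disease_table(res_paths["gene_disease"], universe)
            if "gene_disease" in res_paths else None
        )
        homology = read_homology_table(res_paths["homology"]) if "homology" in res_paths else None
        markers_raw = None
        if "markers" in res_paths:
            mdf = pd.read_csv(res_paths["markers"], sep="\t")
            markers_raw = {
                ct: set(sub["mouse_entrez_id"].astype(int))
                for ct, sub in mdf.groupby("cell_type")
            }
        ct_expr = (
            pd.read_csv(res_paths["celltype_expression"], sep="\t", index_col=0)
            if "celltype_expression" in res_paths else None
        )
    else:
        pathways = _restrict_collection(resources.pathways, universe)
        diseases = _restrict_collection(resources.diseases, universe)
        homology = resources.homology
        markers_raw = resources.markers
        ct_expr = resources.ct_expr

    marker_coll = None
    if markers_raw is not None and homology is not None:
        marker_coll = _enr.map_markers_to_human(markers_raw, homology, universe)

    _stage("differential expression")
    calls: dict[str, tuple[list, list]] = {}
    meta_tables: dict[str, pd.DataFrame] = {}
    for target, comparison in cfg.targets.items():
        effects = pd.concat(
            [_de.donor_de(gm, assignment, target, comparison) for gm in gms],
            ignore_index=True,
        )
        effects.to_csv(out / f"effects_{target}.tsv", sep="\t", index=False)
        written[f"effects_{target}"] = out / f"effects_{target}.tsv"
        meta = _de.meta_analyze(effects, summary_test=cfg.summary_test)
        meta["p_bh"] = _de.bh_adjust(meta["p"].to_numpy())
        up, down = _de.call_de(meta, fc_thresh=cfg.fc_thresh, alpha=cfg.alpha)
        meta["call"] = "none"
        meta.loc[meta["gene"].isin(up), "call"] = "up"
        meta.loc[meta["gene"].isin(down), "call"] = "down"
        meta.to_csv(out / f"meta_{target}.tsv", sep="\t", index=False)
        written[f"meta_{target}"] = out / f"meta_{target}.tsv"
        for direction, genes in (("up", up), ("down", down)):
            p = out / f"{direction}_{target}.txt"
            p.write_text("".join(f"{g}\n" for g in genes))
            written[f"{direction}_{target}"] = p
        calls[target] = (up, down)
        meta_tables[target] = meta

    _stage("differential stability")
    ds = _de.differential_stability(gms)
    ds.to_csv(out / "differential_stability.tsv", sep="\t", index=False)
    written["differential_stability"] = out / "differential_stability.tsv"

    _stage("enrichment")
    for target, (up, down) in calls.items():
        gene_list = {"up": up, "down": down, "all": sorted(set(up) | set(down))}[
            cfg.enrich_direction
        ]
        families = []
        if pathways is not None:
            families.append(("pathways", pathways, cfg.pathway_min_set))
        if marker_coll is not None:
            families.append(
                ("celltypes", marker_coll.to_collection(universe), cfg.marker_min_set)
            )
        if diseases is not None:
            families.append(("diseases", diseases, cfg.disease_min_set))
        for fam_name, coll, min_set in families:
            res = _enr.enrich_collection(gene_list, coll, min_set=min_set, alpha=cfg.alpha)
            p = out / f"enrichment_{fam_name}_{target}.tsv"
            res.to_csv(p, sep="\t", index=False)
            written[f"enrichment_{fam_name}_{target}"] = p

    if ct_expr is not None:
        _stage("ewce")
        spec = _ewce.specificity_matrix(ct_expr)
        for ti, (target, (up, down)) in enumerate(calls.items()):
            gene_list = {"up": up, "down": down, "all": sorted(set(up) | set(down))}[
                cfg.enrich_direction
            ]
            gene_list = [g for g in gene_list if g in spec.spec.index]
            if not gene_list:
                logger.warning("ewce: empty target list for %s; skipped", target)
                continue
            res = _ewce.ewce_test(
                gene_list, spec, reps=cfg.ewce_reps, seed=np.random.SeedSequence(
                    [cfg.seed, 2000 + ti]
                ).generate_state(1)[0] % (2**31),
            )
            p = out / f"ewce_{target}.tsv"
            res.to_csv(p, sep="\t", index=False)
            written[f"ewce_{target}"] = p

    _stage("report")
    if marker_coll is not None:
        zs = [_report.zscore_by_donor(gm) for gm in gms]
        mat, cnt = _report.celltype_network_matrix(zs, marker_coll, assignment, atlas.labels)
        mat.to_csv(out / "celltype_network_matrix.tsv", sep="\t")
        written["celltype_network_matrix"] = out / "celltype_network_matrix.tsv"
        cnt.to_csv(out / "celltype_network_counts.tsv", sep="\t")
        written["celltype_network_counts"] = out / "celltype_network_counts.tsv"
    if len(calls) == 2:
        (t1, (up1, down1)), (t2, (up2, down2)) = calls.items()
        ov = _report.overlap_table(up1, down1, up2, down2, labels=(t1, t2))
        ov.assign(overlap_genes=ov["overlap_genes"].map(lambda g: ",".join(map(str, g)))).to_csv(
            out / "overlap.tsv", sep="\t"
        )
        written["overlap"] = out / "overlap.tsv"
    if truth is not None:
        truth.to_json(out / "truth.json")
        written["truth"] = out / "truth.json"

    manifest = {
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "universe_size": len(universe),
        "n_donors": len(gms),
        "calls": {t: {"n_up": len(u), "n_down": len(d)} for t, (u, d) in calls.items()},
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(written.items())
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _restrict_collection(coll, universe):
    from .io import GeneSet, GeneSetCollection

    return GeneSetCollection(
        name=coll.name,
        sets={k: GeneSet(label=v.label, genes=v.genes & frozenset(universe))
              for k, v in coll.sets.items()},
        universe=frozenset(universe),
    )
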