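"""Synthetic multi-donor brain-expression datasets with known ground truth.

The generator emulates the structure of a six-donor postmortem microarray
atlas: per-donor probe x sample log2 expression with presence/absence flags,
probe annotations (including missing-Entrez and never-present probes),
sample annotations with MNI coordinates and structure acronyms, nine
non-overlapping network masks on a voxel grid, and gene-set resources
(cell-type markers with a mouse->human homology table, pathways, diseases,
and a cell-type mean-expression matrix).

The expression model is additive Gaussian on the log2 scale:

    log2 x[g, s] = baseline[g] + donor_shift[d, g]
                   + effect[d, g] * 1{sample s in g's planted network}
                   + structure_effect[g, structure(s)]   (stable genes)
                   + N(0, noise_sd)

Planted network effects are heterogeneous across donors
(effect[d, g] = nominal[g] + N(0, effect_tau)) so that between-donor
variance estimation is exercised.  Structure-level effects are shared across
donors (giving those genes donor-consistent regional profiles, hence high
differential stability) and are mean-centered within each network's
structures so they stay null for network contrasts.  Probes replicate the
gene signal plus probe-specific noise; one designated high-fidelity probe
per gene (lowest noise) is recorded in the truth.  The nine box masks are
mirror-symmetric about the mid-sagittal plane so that mirrored
right-hemisphere samples of bi-hemispheric donors still fall inside their
generating mask.

Seeding: every generator derives independent streams from the config seed as
``default_rng([seed, stream_index])``; identical configs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DonorBundle,
    GeneSet,
    GeneSetCollection,
    HomologyMap,
    write_donor_bundle,
    write_gene_sets_gmt,
    write_homology_table,
    write_network_masks,
)
from .mapping import NetworkAtlas

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticResources",
    "generate_atlas",
    "generate_dataset",
    "generate_gene_sets",
    "write_synthetic",
]

_MOUSE_OFFSET = 100_000
_COLLISION_OFFSET = 200_000


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults: the reference scenario).

    Defaults emulate the reduced-scale reference conditions: 6 donors (2
    bi-hemispheric), 2,000 genes, 9 networks with ~40 samples per network
    per donor, 100 planted genes at |log2 FC| in [1.2, 2.0], residual log2
    noise 0.5, and between-donor effect heterogeneity 0.15.
    """

    seed: int = 0
    n_donors: int = 6
    n_bihemispheric: int = 2
    n_genes: int = 2000
    networks: tuple = tuple("ABCDEFGHI")
    samples_per_network: int = 40
    background_samples: int = 40
    structures_per_network: int = 4
    n_background_structures: int = 4
    grid_shape: tuple = (16, 32, 32)
    voxel_size_mm: float = 2.0
    # planted network effects: network -> (n_up, n_down, (lo, hi))
    planted: dict = field(
        default_factory=lambda: {"C": (25, 25, (1.2, 2.0)), "D": (25, 25, (1.2, 2.0))}
    )
    effect_tau: float = 0.15
    noise_sd: float = 0.5
    n_stable_genes: int = 200
    structure_effect_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    donor_shift_sd: float = 0.3
    probes_per_gene_probs: dict = field(
        default_factory=lambda: {1: 0.35, 2: 0.40, 3: 0.20, 4: 0.05}
    )
    probe_noise_best: float = 0.1
    probe_noise_range: tuple = (0.3, 0.8)
    pa_present_prob: float = 0.995
    frac_absent_probes: float = 0.03
    frac_missing_entrez: float = 0.05
    # gene-set resources
    n_cell_types: int = 14
    markers_per_celltype: tuple = (8, 15)
    n_small_celltypes: int = 2
    positive_celltype: str = "thalamus_cholinergic"
    positive_marker_size: int = 10
    n_collisions: int = 1
    n_unmapped_markers: int = 2
    n_pathways: int = 30
    pathway_size_range: tuple = (10, 60)
    n_tiny_pathways: int = 2
    positive_pathway_frac: float = 0.7
    n_diseases: int = 40
    disease_size_range: tuple = (5, 80)
    positive_disease_frac: float = 0.6
    marker_boost: float = 8.0

    def __post_init__(self) -> None:
        if self.n_bihemispheric > self.n_donors:
            raise ValueError("more bi-hemispheric donors than donors")
        for net, (n_up, n_down, (lo, hi)) in self.planted.items():
            if net not in self.networks:
                raise ValueError(f"planted network {net!r} not in networks")
            if lo <= 0 or hi < lo:
                raise ValueError("planted effect sizes must be positive, lo <= hi")
        n_planted = sum(u + d for u, d, _ in self.planted.values())
        if n_planted + self.n_stable_genes > self.n_genes:
            raise ValueError("not enough genes for planted + stable sets")

    @property
    def donor_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    def structures(self, network: str | None) -> list[str]:
        if network is None:
            return [f"BG_s{i + 1}" for i in range(self.n_background_structures)]
        return [f"{network}_s{i + 1}" for i in range(self.structures_per_network)]


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every pipeline stage."""

    planted: pd.DataFrame  # columns: gene, network, direction, effect
    stable_genes: list
    genes: list
    sample_networks: pd.DataFrame  # donor_id, sample_id, network (None = outside)
    best_probe: dict
    config: SyntheticConfig

    def planted_genes(self, network: str | None = None, direction: str | None = None) -> list:
        df = self.planted
        if network is not None:
            df = df[df["network"] == network]
        if direction is not None:
            df = df[df["direction"] == direction]
        return df["gene"].tolist()

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "planted": self.planted.to_dict(orient="records"),
            "stable_genes": [int(g) for g in self.stable_genes],
            "genes": [int(g) for g in self.genes],
            "sample_networks": self.sample_networks.to_dict(orient="records"),
            "best_probe": {str(k): v for k, v in self.best_probe.items()},
            "config": _config_to_jsonable(self.config),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = config_from_dict(payload["config"])
        planted = pd.DataFrame(
            payload["planted"], columns=["gene", "network", "direction", "effect"]
        )
        sn = pd.DataFrame(
            payload["sample_networks"], columns=["donor_id", "sample_id", "network"]
        )
        return cls(
            planted=planted,
            stable_genes=[int(g) for g in payload["stable_genes"]],
            genes=[int(g) for g in payload["genes"]],
            sample_networks=sn,
            best_probe={int(k): v for k, v in payload["best_probe"].items()},
            config=cfg,
        )


def _config_to_jsonable(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["networks"] = list(cfg.networks)
    d["probes_per_gene_probs"] = {str(k): v for k, v in cfg.probes_per_gene_probs.items()}
    return d


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    if "networks" in d:
        d["networks"] = tuple(d["networks"])
    if "probes_per_gene_probs" in d:
        d["probes_per_gene_probs"] = {int(k): v for k, v in d["probes_per_gene_probs"].items()}
    if "planted" in d:
        d["planted"] = {
            net: (int(v[0]), int(v[1]), (float(v[2][0]), float(v[2][1])))
            for net, v in d["planted"].items()
        }
    for key in ("grid_shape", "markers_per_celltype", "pathway_size_range",
                "disease_size_range", "probe_noise_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


def generate_atlas(cfg: SyntheticConfig) -> NetworkAtlas:
    """Nine disjoint axis-aligned box masks, mirror-symmetric in x.

    The affine centers the grid on the origin at ``voxel_size_mm`` isotropic
    resolution; the nine boxes tile a 3x3 arrangement in (j, k) with >=
    1-voxel gaps and share a symmetric i-extent so that the x -> -x mirror
    maps every mask onto itself.
    """
    nx, ny, nz = cfg.grid_shape
    if len(cfg.networks) != 9:
        raise ValueError("generator expects exactly 9 network labels")
    if nx < 7 or ny < 30 or nz < 30:
        raise ValueError(f"grid {cfg.grid_shape} too small for 9 disjoint boxes")
    s = float(cfg.voxel_size_mm)
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = [-s * (n - 1) / 2.0 for n in (nx, ny, nz)]
    masks = np.zeros((9, nx, ny, nz), dtype=bool)
    i_lo, i_hi = 2, nx - 3  # symmetric: mirror(i) = (nx - 1) - i
    for idx in range(9):
        bj, bk = divmod(idx, 3)
        j0, k0 = bj * 10 + 1, bk * 10 + 1
        masks[idx, i_lo : i_hi + 1, j0 : j0 + 8, k0 : k0 + 8] = True
    return NetworkAtlas(labels=list(cfg.networks), masks=masks, affine=affine)


def _left_voxels(mask: np.ndarray, nx: int) -> np.ndarray:
    """Voxel indices of the mask's x < 0 half (i < (nx-1)/2)."""
    ijk = np.argwhere(mask)
    return ijk[ijk[:, 0] < (nx - 1) / 2.0]


def _draw_samples(
    rng: np.random.Generator,
    voxels_left: np.ndarray,
    n: int,
    bihemispheric: bool,
    atlas: NetworkAtlas,
    voxel_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n sample coordinates (mm) from left-half voxels; mirror some to
    the right hemisphere for bi-hemispheric donors.  Returns (mm, hemi)."""
    nx = atlas.grid_shape[0]
    picks = voxels_left[rng.integers(0, len(voxels_left), size=n)]
    mirror = np.zeros(n, dtype=bool)
    if bihemispheric:
        mirror[: n // 2] = True  # first half of draws become right-hemisphere
    ijk = picks.copy()
    ijk[mirror, 0] = (nx - 1) - ijk[mirror, 0]
    homog = np.column_stack([ijk, np.ones(n)]).astype(float)
    mm = (atlas.affine @ homog.T).T[:, :3]
    mm += rng.uniform(-0.49, 0.49, size=mm.shape) * voxel_size
    hemi = np.where(mm[:, 0] > 0, "R", "L")
    return mm, hemi


def generate_dataset(
    cfg: SyntheticConfig, atlas: NetworkAtlas
) -> tuple[list[DonorBundle], SyntheticTruth]:
    """Generate per-donor probe-level bundles plus the ground truth."""
    nx = atlas.grid_shape[0]
    rng_alloc = np.random.default_rng([cfg.seed, 0])

    genes = np.arange(1001, 1001 + cfg.n_genes)
    perm = rng_alloc.permutation(genes)
    cursor = 0
    planted_rows = []
    for net in sorted(cfg.planted):
        n_up, n_down, (lo, hi) = cfg.planted[net]
        for direction, count in (("up", n_up), ("down", n_down)):
            block = perm[cursor : cursor + count]
            cursor += count
            effects = rng_alloc.uniform(lo, hi, size=count)
            if direction == "down":
                effects = -effects
            for g, e in zip(block, effects):
                planted_rows.append(
                    {"gene": int(g), "network": net, "direction": direction, "effect": float(e)}
                )
    planted = pd.DataFrame(planted_rows, columns=["gene", "network", "direction", "effect"])
    stable_genes = [int(g) for g in perm[cursor : cursor + cfg.n_stable_genes]]
    cursor += cfg.n_stable_genes

    # donor-consistent structure effects for stable genes, centered per network
    all_structures: list[str] = []
    for net in cfg.networks:
        all_structures.extend(cfg.structures(net))
    all_structures.extend(cfg.structures(None))
    struct_eff = pd.DataFrame(
        0.0, index=pd.Index(genes, name="gene"), columns=all_structures
    )
    if stable_genes:
        eff = rng_alloc.normal(0.0, cfg.structure_effect_sd,
                               size=(len(stable_genes), len(all_structures)))
        block_sizes = [cfg.structures_per_network] * len(cfg.networks) + [
            cfg.n_background_structures
        ]
        start = 0
        for size in block_sizes:  # center within each network's structure group
            eff[:, start : start + size] -= eff[:, start : start + size].mean(
                axis=1, keepdims=True
            )
            start += size
        struct_eff.loc[stable_genes, :] = eff

    baseline = rng_alloc.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    # probe layout (shared across donors)
    counts_options = np.array(sorted(cfg.probes_per_gene_probs))
    probs = np.array([cfg.probes_per_gene_probs[k] for k in counts_options], dtype=float)
    probs = probs / probs.sum()
    probes_per_gene = rng_alloc.choice(counts_options, size=cfg.n_genes, p=probs)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    probe_sd: list[float] = []
    best_probe: dict[int, str] = {}
    lo_sd, hi_sd = cfg.probe_noise_range
    for gi, (g, npr) in enumerate(zip(genes, probes_per_gene)):
        best = int(rng_alloc.integers(0, npr))
        for j in range(int(npr)):
            pid = f"{g}_p{j + 1}"
            probe_ids.append(pid)
            probe_gene_idx.append(gi)
            if j == best:
                probe_sd.append(cfg.probe_noise_best)
                best_probe[int(g)] = pid
            else:
                probe_sd.append(float(rng_alloc.uniform(lo_sd, hi_sd)))
    n_base = len(probe_ids)
    n_absent = int(round(cfg.frac_absent_probes * n_base))
    n_missing = int(round(cfg.frac_missing_entrez * n_base))
    absent_ids = [f"absent_p{i + 1}" for i in range(n_absent)]
    missing_ids = [f"noentrez_p{i + 1}" for i in range(n_missing)]
    all_probe_ids = probe_ids + absent_ids + missing_ids
    entrez_col = pd.array(
        [int(genes[gi]) for gi in probe_gene_idx]
        + [900_001 + i for i in range(n_absent)]
        + [None] * n_missing,
        dtype="Int64",
    )
    probe_table = pd.DataFrame({"entrez_id": entrez_col},
                               index=pd.Index(all_probe_ids, name="probe_id"))
    probe_sd_arr = np.asarray(probe_sd)
    gene_idx_arr = np.asarray(probe_gene_idx)

    # per-donor planted effect realizations (nominal + heterogeneity)
    effect_by_gene = planted.set_index("gene")["effect"]
    effect_network = planted.set_index("gene")["network"]

    left_by_net = [_left_voxels(atlas.masks[i], nx) for i in range(len(atlas.labels))]
    outside = ~atlas.masks.any(axis=0)
    left_bg = _left_voxels(outside, nx)

    bundles: list[DonorBundle] = []
    sample_net_rows = []
    for di, donor in enumerate(cfg.donor_ids):
        rng = np.random.default_rng([cfg.seed, 1 + di])
        bihemi = di < cfg.n_bihemispheric
        sample_mm = []
        sample_hemi = []
        sample_struct = []
        sample_net: list = []
        for li, net in enumerate(atlas.labels):
            mm, hemi = _draw_samples(
                rng, left_by_net[li], cfg.samples_per_network, bihemi, atlas, cfg.voxel_size_mm
            )
            structs = rng.choice(cfg.structures(net), size=cfg.samples_per_network)
            sample_mm.append(mm)
            sample_hemi.append(hemi)
            sample_struct.extend(structs)
            sample_net.extend([net] * cfg.samples_per_network)
        if cfg.background_samples:
            mm, hemi = _draw_samples(
                rng, left_bg, cfg.background_samples, bihemi, atlas, cfg.voxel_size_mm
            )
            structs = rng.choice(cfg.structures(None), size=cfg.background_samples)
            sample_mm.append(mm)
            sample_hemi.append(hemi)
            sample_struct.extend(structs)
            sample_net.extend([None] * cfg.background_samples)
        mm = np.vstack(sample_mm)
        hemi = np.concatenate(sample_hemi)
        n_samples = len(mm)
        sample_ids = [f"{donor}_s{i + 1:04d}" for i in range(n_samples)]

        donor_shift = rng.normal(0.0, cfg.donor_shift_sd, size=cfg.n_genes)
        donor_effect = effect_by_gene + rng.normal(0.0, cfg.effect_tau, size=len(effect_by_gene))

        signal = baseline[:, None] + donor_shift[:, None] + np.zeros((cfg.n_genes, n_samples))
        gene_pos = {int(g): i for i, g in enumerate(genes)}
        net_arr = np.array([n if n is not None else "" for n in sample_net])
        for g, net in effect_network.items():
            signal[gene_pos[int(g)], net_arr == net] += donor_effect[g]
        se = struct_eff.to_numpy()
        struct_pos = {s: i for i, s in enumerate(all_structures)}
        struct_idx = np.array([struct_pos[s] for s in sample_struct])
        signal += se[:, struct_idx]
        signal += rng.normal(0.0, cfg.noise_sd, size=signal.shape)

        probe_expr = signal[gene_idx_arr, :] + rng.normal(
            0.0, 1.0, size=(n_base, n_samples)
        ) * probe_sd_arr[:, None]
        pa = rng.random(size=(n_base, n_samples)) < cfg.pa_present_prob
        absent_expr = rng.normal(4.0, 1.0, size=(n_absent, n_samples))
        missing_expr = rng.normal(6.0, 1.0, size=(n_missing, n_samples))
        expr_all = np.vstack([probe_expr, absent_expr, missing_expr])
        pa_all = np.vstack(
            [
                pa,
                np.zeros((n_absent, n_samples), dtype=bool),
                rng.random(size=(n_missing, n_samples)) < cfg.pa_present_prob,
            ]
        )
        expr = pd.DataFrame(expr_all, index=probe_table.index.rename(None), columns=sample_ids)
        pa_df = pd.DataFrame(pa_all, index=probe_table.index.rename(None), columns=sample_ids)
        samples = pd.DataFrame(
            {
                "structure_acronym": sample_struct,
                "hemisphere": hemi,
                "mni_x": mm[:, 0],
                "mni_y": mm[:, 1],
                "mni_z": mm[:, 2],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        bundles.append(
            DonorBundle(donor_id=donor, expr=expr, pa=pa_df, probes=probe_table, samples=samples)
        )
        for sid, net in zip(sample_ids, sample_net):
            sample_net_rows.append({"donor_id": donor, "sample_id": sid, "network": net})

    truth = SyntheticTruth(
        planted=planted,
        stable_genes=stable_genes,
        genes=[int(g) for g in genes],
        sample_networks=pd.DataFrame(sample_net_rows,
                                     columns=["donor_id", "sample_id", "network"]),
        best_probe=best_probe,
        config=cfg,
    )
    return bundles, truth


@dataclass
class SyntheticResources:
    """Gene-set resources with their planted positives recorded."""

    markers: dict  # cell type -> set of MOUSE Entrez IDs
    homology: HomologyMap
    pathways: GeneSetCollection
    diseases: GeneSetCollection
    ct_expr: pd.DataFrame  # human gene x cell type mean linear expression
    positive_celltype: str
    positive_pathway: str
    positive_disease: str
    collision_genes: frozenset  # human IDs claimed by two mouse sources
    unmapped_mouse: frozenset


def generate_gene_sets(truth: SyntheticTruth, cfg: SyntheticConfig) -> SyntheticResources:
    """Marker/pathway/disease resources with one planted positive set each.

    The positive marker set, pathway, and disease draw most of their genes
    from the planted upregulated genes; the homology table contains
    ``n_collisions`` many-to-one mouse->human collisions and omits
    ``n_unmapped_markers`` mouse markers entirely.
    """
    rng = np.random.default_rng([cfg.seed, 1000])
    universe = np.array(truth.genes)
    planted_up = np.array(truth.planted_genes(direction="up"))
    if len(planted_up) < cfg.positive_marker_size:
        raise ValueError("not enough planted up-genes for the positive marker set")

    # --- cell-type markers (human composition first, then mouse IDs) ---
    human_sets: dict[str, np.ndarray] = {}
    pos_markers = rng.choice(planted_up, size=cfg.positive_marker_size, replace=False)
    human_sets[cfg.positive_celltype] = pos_markers
    n_other = cfg.n_cell_types - 1 - cfg.n_small_celltypes
    lo, hi = cfg.markers_per_celltype
    non_planted = np.setdiff1d(universe, planted_up)
    for i in range(n_other):
        size = int(rng.integers(lo, hi + 1))
        human_sets[f"celltype_{i + 1:02d}"] = rng.choice(non_planted, size=size, replace=False)
    for i in range(cfg.n_small_celltypes):
        size = int(rng.integers(3, 6))  # below the 6-marker testing minimum
        human_sets[f"small_celltype_{i + 1}"] = rng.choice(non_planted, size=size, replace=False)

    markers = {ct: {int(h) + _MOUSE_OFFSET for h in hs} for ct, hs in human_sets.items()}
    pairs = [(int(h) + _MOUSE_OFFSET, int(h)) for hs in human_sets.values() for h in hs]

    # unmapped mouse markers: homology rows removed
    other_cts = [ct for ct in human_sets if ct != cfg.positive_celltype]
    unmapped: set[int] = set()
    flat = sorted({int(h) for ct in other_cts for h in human_sets[ct]})
    for h in rng.choice(flat, size=min(cfg.n_unmapped_markers, len(flat)), replace=False):
        unmapped.add(int(h) + _MOUSE_OFFSET)
    pairs = [(m, h) for m, h in pairs if m not in unmapped]

    # collisions: second mouse source for an existing human marker, placed in
    # a different cell type
    collision_humans: set[int] = set()
    eligible = [h for h in flat if (h + _MOUSE_OFFSET) not in unmapped]
    take = min(cfg.n_collisions, len(eligible))
    for h in rng.choice(np.array(eligible), size=take, replace=False):
        h = int(h)
        m2 = h + _COLLISION_OFFSET
        host_ct = next(ct for ct in other_cts if h in set(int(x) for x in human_sets[ct]))
        # keep the planted positive set clean: collisions land in another set
        other = next(ct for ct in other_cts if ct != host_ct)
        markers[other].add(m2)
        pairs.append((m2, h))
        collision_humans.add(h)
    homology = HomologyMap(pairs=pd.DataFrame(pairs, columns=["source_id", "target_id"]))

    # --- pathways (GMT) ---
    plo, phi = cfg.pathway_size_range
    psize = int(rng.integers(plo, phi + 1))
    n_pos = min(int(round(cfg.positive_pathway_frac * psize)), len(planted_up))
    pos_path = set(
        int(g) for g in rng.choice(planted_up, size=n_pos, replace=False)
    ) | set(int(g) for g in rng.choice(non_planted, size=psize - n_pos, replace=False))
    path_sets: dict[str, GeneSet] = {
        "PW_POS": GeneSet(label="planted positive pathway", genes=frozenset(pos_path))
    }
    for i in range(cfg.n_pathways - 1):
        size = int(rng.integers(plo, phi + 1))
        genes = frozenset(int(g) for g in rng.choice(universe, size=size, replace=False))
        path_sets[f"PW_{i + 1:03d}"] = GeneSet(label=f"pathway {i + 1}", genes=genes)
    for i in range(cfg.n_tiny_pathways):
        genes = frozenset(
            int(g) for g in rng.choice(universe, size=int(rng.integers(3, 10)), replace=False)
        )
        path_sets[f"PW_TINY_{i + 1}"] = GeneSet(label=f"tiny pathway {i + 1}", genes=genes)
    pathways = GeneSetCollection(name="pathways", sets=path_sets,
                                 universe=frozenset(int(g) for g in universe))

    # --- diseases ---
    dlo, dhi = cfg.disease_size_range
    dsize = int(rng.integers(max(dlo, 10), dhi + 1))
    n_pos = min(int(round(cfg.positive_disease_frac * dsize)), len(planted_up))
    pos_dis = set(
        int(g) for g in rng.choice(planted_up, size=n_pos, replace=False)
    ) | set(int(g) for g in rng.choice(non_planted, size=dsize - n_pos, replace=False))
    dis_sets: dict[str, GeneSet] = {
        "DIS_POS": GeneSet(label="planted positive disease", genes=frozenset(pos_dis))
    }
    for i in range(cfg.n_diseases - 1):
        size = int(rng.integers(dlo, dhi + 1))
        genes = frozenset(int(g) for g in rng.choice(universe, size=size, replace=False))
        dis_sets[f"DIS_{i + 1:03d}"] = GeneSet(label=f"disease {i + 1}", genes=genes)
    diseases = GeneSetCollection(name="diseases", sets=dis_sets,
                                 universe=frozenset(int(g) for g in universe))

    # --- cell-type mean-expression matrix (linear scale) ---
    cts = list(human_sets)
    base = rng.lognormal(mean=1.0, sigma=0.5, size=(len(universe), len(cts)))
    ct_expr = pd.DataFrame(base, index=pd.Index(universe, name="gene"), columns=cts)
    for ct, hs in human_sets.items():
        ct_expr.loc[[int(h) for h in hs], ct] *= cfg.marker_boost
    return SyntheticResources(
        markers=markers,
        homology=homology,
        pathways=pathways,
        diseases=diseases,
        ct_expr=ct_expr,
        positive_celltype=cfg.positive_celltype,
        positive_pathway="PW_POS",
        positive_disease="DIS_POS",
        collision_genes=frozenset(collision_humans),
        unmapped_mouse=frozenset(unmapped),
    )


def write_synthetic(
    out_dir,
    bundles: Sequence[DonorBundle],
    atlas: NetworkAtlas,
    truth: SyntheticTruth,
    resources: SyntheticResources | None = None,
) -> dict:
    """Write bundles, masks, resources and truth.json; returns a manifest dict."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"donors": [], "atlas": {}, "resources": {}}
    for b in bundles:
        paths = write_donor_bundle(b, out_dir / "donors" / b.donor_id)
        manifest["donors"].append(
            {"donor_id": b.donor_id, **{k: str(p) for k, p in paths.items()}}
        )
    mask_paths = write_network_masks(atlas, out_dir / "masks")
    manifest["atlas"] = {
        "labels": atlas.labels,
        "paths": [str(p) for p in mask_paths],
    }
    truth.to_json(out_dir / "truth.json")
    manifest["truth"] = str(out_dir / "truth.json")
    if resources is not None:
        res_dir = out_dir / "resources"
        res_dir.mkdir(exist_ok=True)
        write_gene_sets_gmt(resources.pathways, res_dir / "pathways.gmt")
        write_homology_table(resources.homology, res_dir / "homology.tsv")
        rows = [
            {"gene_id": g, "disease_id": did, "disease_name": gs.label}
            for did, gs in resources.diseases.sets.items()
            for g in sorted(gs.genes)
        ]
        pd.DataFrame(rows, columns=["gene_id", "disease_id", "disease_name"]).to_csv(
            res_dir / "gene_disease.tsv", sep="\t", index=False
        )
        marker_rows = [
            {"cell_type": ct, "mouse_entrez_id": m}
            for ct, ms in resources.markers.items()
            for m in sorted(ms)
        ]
        pd.DataFrame(marker_rows, columns=["cell_type", "mouse_entrez_id"]).to_csv(
            res_dir / "markers.tsv", sep="\t", index=False
        )
        resources.ct_expr.to_csv(res_dir / "celltype_expression.tsv", sep="\t")
        manifest["resources"] = {
            "pathways": str(res_dir / "pathways.gmt"),
            "homology": str(res_dir / "homology.tsv"),
            "gene_disease": str(res_dir / "gene_disease.tsv"),
            "markers": str(res_dir / "markers.tsv"),
            "celltype_expression": str(res_dir / "celltype_expression.tsv"),
        }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
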