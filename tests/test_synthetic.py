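"""Generator guarantees: determinism, disjoint masks, truth bookkeeping,
planted resources, and round trips."""

import numpy as np
import pandas as pd
import pytest

from scntx.enrichment import map_markers_to_human
from scntx.io import write_gene_sets_gmt
from scntx.mapping import assign_samples
from scntx.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    generate_atlas,
    generate_dataset,
    generate_gene_sets,
    write_synthetic,
)


def tiny_cfg(**kw):
    base = dict(
        seed=3,
        n_genes=120,
        samples_per_network=8,
        background_samples=5,
        n_stable_genes=10,
        planted={"C": (5, 5, (1.2, 2.0)), "D": (5, 5, (1.2, 2.0))},
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestAtlas:
    def test_nine_disjoint_masks(self):
        atlas = generate_atlas(tiny_cfg())
        assert len(atlas.labels) == 9
        assert not (atlas.masks.sum(axis=0) > 1).any()
        assert (atlas.masks.sum(axis=(1, 2, 3)) > 0).all()

    def test_deterministic_and_label_order(self):
        cfg = tiny_cfg()
        a1, a2 = generate_atlas(cfg), generate_atlas(cfg)
        np.testing.assert_array_equal(a1.masks, a2.masks)
        assert a1.labels == list(cfg.networks)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_atlas(tiny_cfg(grid_shape=(6, 12, 12)))

    def test_masks_mirror_symmetric_in_x(self):
        atlas = generate_atlas(tiny_cfg())
        nx = atlas.grid_shape[0]
        np.testing.assert_array_equal(atlas.masks, atlas.masks[:, ::-1, :, :])
        # symmetry axis: mirror voxel (nx-1)-i maps mask onto itself
        assert nx % 2 == 0


class TestDataset:
    def test_truth_bookkeeping(self):
        cfg = tiny_cfg()
        bundles, truth = generate_dataset(cfg, generate_atlas(cfg))
        planted_c_up = truth.planted.query("network == 'C' and direction == 'up'")
        assert len(planted_c_up) == 5
        assert (planted_c_up["effect"] >= 1.2).all() and (planted_c_up["effect"] <= 2.0).all()
        down = truth.planted.query("direction == 'down'")["effect"]
        assert (down <= -1.2).all()
        # planted sets disjoint across networks and directions
        assert truth.planted["gene"].is_unique
        assert not set(truth.planted["gene"]) & set(truth.stable_genes)

    def test_same_seed_identical_different_seed_differs(self):
        cfg = tiny_cfg()
        atlas = generate_atlas(cfg)
        b1, _ = generate_dataset(cfg, atlas)
        b2, _ = generate_dataset(cfg, atlas)
        pd.testing.assert_frame_equal(b1[0].expr, b2[0].expr)
        b3, _ = generate_dataset(tiny_cfg(seed=4), atlas)
        assert not b1[0].expr.equals(b3[0].expr)

    def test_bihemispheric_and_left_only_donors(self):
        cfg = tiny_cfg()
        bundles, _ = generate_dataset(cfg, generate_atlas(cfg))
        hemis = [set(b.samples["hemisphere"]) for b in bundles]
        assert hemis[0] == {"L", "R"}  # bi-hemispheric donor
        for h in hemis[cfg.n_bihemispheric:]:
            assert h == {"L"}
        for b in bundles[cfg.n_bihemispheric:]:
            assert (b.samples["mni_x"] < 0).all()

    def test_closure_under_mapping(self):
        cfg = tiny_cfg(seed=9)
        atlas = generate_atlas(cfg)
        bundles, truth = generate_dataset(cfg, atlas)
        asg = assign_samples(atlas, bundles)
        merged = asg.merge(truth.sample_networks, on=["donor_id", "sample_id"])
        assert (
            merged["network_label"].fillna("none") == merged["network"].fillna("none")
        ).all()

    def test_probe_annotations(self):
        cfg = tiny_cfg()
        bundles, truth = generate_dataset(cfg, generate_atlas(cfg))
        probes = bundles[0].probes
        assert probes["entrez_id"].isna().sum() > 0  # missing-Entrez probes exist
        absent = bundles[0].pa.loc[probes.index.str.startswith("absent")]
        assert not absent.to_numpy().any()  # never above background
        # designated high-fidelity probe exists for every gene
        assert set(truth.best_probe) == set(truth.genes)

    def test_truth_json_round_trip(self, tmp_path):
        cfg = tiny_cfg()
        _, truth = generate_dataset(cfg, generate_atlas(cfg))
        p = truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(p)
        pd.testing.assert_frame_equal(back.planted, truth.planted)
        assert back.stable_genes == truth.stable_genes
        assert back.best_probe == truth.best_probe
        assert back.config == cfg


class TestGeneSets:
    def test_collision_construction_and_removal(self):
        cfg = tiny_cfg()
        _, truth = generate_dataset(cfg, generate_atlas(cfg))
        res = generate_gene_sets(truth, cfg)
        assert len(res.collision_genes) == cfg.n_collisions
        h = next(iter(res.collision_genes))
        sources = res.homology.pairs.query("target_id == @h")["source_id"]
        assert len(sources) == 2  # two mouse IDs claim one human gene
        mc = map_markers_to_human(res.markers, res.homology, set(truth.genes))
        for genes in mc.cell_types.values():
            assert h not in genes

    def test_positive_sets_planted(self):
        cfg = tiny_cfg()
        _, truth = generate_dataset(cfg, generate_atlas(cfg))
        res = generate_gene_sets(truth, cfg)
        up = set(truth.planted_genes(direction="up"))
        pos_path = res.pathways.sets[res.positive_pathway].genes
        assert len(pos_path & up) >= int(0.5 * len(pos_path))
        pos_markers = {h - 100_000 for h in res.markers[res.positive_celltype]}
        assert pos_markers <= up

    def test_small_cell_types_below_marker_minimum(self):
        cfg = tiny_cfg()
        _, truth = generate_dataset(cfg, generate_atlas(cfg))
        res = generate_gene_sets(truth, cfg)
        small = [ct for ct in res.markers if ct.startswith("small_")]
        assert len(small) == cfg.n_small_celltypes
        for ct in small:
            assert len(res.markers[ct]) < 6

    def test_gmt_bytes_deterministic(self, tmp_path):
        cfg = tiny_cfg()
        _, truth = generate_dataset(cfg, generate_atlas(cfg))
        r1 = generate_gene_sets(truth, cfg)
        r2 = generate_gene_sets(truth, cfg)
        p1 = write_gene_sets_gmt(r1.pathways, tmp_path / "a.gmt")
        p2 = write_gene_sets_gmt(r2.pathways, tmp_path / "b.gmt")
        assert p1.read_bytes() == p2.read_bytes()


class TestWriteSynthetic:
    def test_manifest_and_files(self, tmp_path):
        cfg = tiny_cfg()
        atlas = generate_atlas(cfg)
        bundles, truth = generate_dataset(cfg, atlas)
        res = generate_gene_sets(truth, cfg)
        manifest = write_synthetic(tmp_path, bundles, atlas, truth, res)
        assert len(manifest["donors"]) == cfg.n_donors
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "resources" / "pathways.gmt").exists()
        assert len(manifest["atlas"]["paths"]) == 9
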