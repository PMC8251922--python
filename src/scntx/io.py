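"""Readers and writers for every external format the pipeline touches.

Formats: delimited TSV/CSV (expression, presence/absence flags, probe and
sample annotations, homology pairs, gene-disease tables), GMT gene sets,
NIfTI-1 network masks.  Readers validate strictly: malformed cells raise
rather than being coerced, and write->read round-trips reproduce the
in-memory object exactly.

Gene identity is integer Entrez throughout; missing Entrez IDs are encoded
as pandas ``<NA>`` (never 0) so that the probe filter can remove them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .mapping import NetworkAtlas

__all__ = [
    "DonorBundle",
    "GeneSet",
    "GeneSetCollection",
    "HomologyMap",
    "read_donor_bundle",
    "write_donor_bundle",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_gene_disease_table",
    "read_homology_table",
    "write_homology_table",
    "read_network_masks",
    "write_network_masks",
]

_SAMPLE_COLUMNS = ("donor_id", "structure_acronym", "hemisphere", "mni_x", "mni_y", "mni_z")


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class DonorBundle:
    """One donor's probe-level expression with annotations.

    ``expr`` and ``pa`` are probe x sample DataFrames sharing index (probe_id)
    and columns (sample_id); ``probes`` is indexed by probe_id with an
    ``entrez_id`` column (nullable Int64); ``samples`` is indexed by sample_id
    with structure_acronym, hemisphere and mni_x/y/z columns.
    """

    donor_id: str
    expr: pd.DataFrame
    pa: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError(f"donor {self.donor_id}: duplicate probe_ids")
        if self.expr.columns.has_duplicates:
            raise ValueError(f"donor {self.donor_id}: duplicate sample_ids")
        if not self.expr.index.equals(self.probes.index):
            raise ValueError(f"donor {self.donor_id}: probe annotation mismatch")
        if not self.expr.columns.equals(pd.Index(self.samples.index)):
            raise ValueError(f"donor {self.donor_id}: sample annotation mismatch")
        if not (self.pa.index.equals(self.expr.index) and self.pa.columns.equals(self.expr.columns)):
            raise ValueError(f"donor {self.donor_id}: PA matrix axis mismatch")
        vals = self.expr.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            raise ValueError(f"donor {self.donor_id}: non-finite or non-numeric expression")
        if self.pa.to_numpy().dtype != bool:
            raise ValueError(f"donor {self.donor_id}: PA matrix is not boolean")
        missing = [c for c in _SAMPLE_COLUMNS[1:] if c not in self.samples.columns]
        if missing:
            raise ValueError(f"donor {self.donor_id}: sample table missing columns {missing}")
        if "entrez_id" not in self.probes.columns:
            raise ValueError(f"donor {self.donor_id}: probe table missing column entrez_id")

    @property
    def n_probes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "DonorBundle":
        idx = pd.Index(probe_ids)
        return DonorBundle(
            donor_id=self.donor_id,
            expr=self.expr.loc[idx],
            pa=self.pa.loc[idx],
            probes=self.probes.loc[idx],
            samples=self.samples,
        )


class GeneSet(NamedTuple):
    label: str
    genes: frozenset


@dataclass
class GeneSetCollection:
    """Named gene sets plus the test universe (all integer Entrez IDs)."""

    name: str
    sets: dict[str, GeneSet]
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        self.universe = frozenset(int(g) for g in self.universe)

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v.genes) for k, v in self.sets.items()}, dtype=int)


@dataclass
class HomologyMap:
    """Mouse->human Entrez homology pairs (duplicates collapsed)."""

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("source_id", "target_id"):
            if col not in self.pairs.columns:
                raise ValueError(f"homology table missing column {col}")
        self.pairs = (
            self.pairs[["source_id", "target_id"]]
            .astype(int)
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def targets_of(self, source_id: int) -> list[int]:
        hit = self.pairs[self.pairs["source_id"] == int(source_id)]
        return hit["target_id"].tolist()


def _read_numeric_matrix(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(f"{kind} file {path}: non-numeric value at row {row!r}, column {col!r}")
    return df


def read_donor_bundle(expr_path, pa_path, probe_path, sample_path) -> DonorBundle:
    """Read one donor's expression, PA flags, probe and sample annotations.

    Delimiter is inferred from the extension (.csv comma, otherwise tab).
    The sample table must carry a single donor_id.
    """
    expr = _read_numeric_matrix(Path(expr_path), "expression")
    if expr.isna().to_numpy().any():
        raise ValueError(f"expression file {expr_path}: missing values")
    pa_raw = _read_numeric_matrix(Path(pa_path), "PA")
    vals = pa_raw.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise ValueError(
            f"PA file {pa_path}: non-boolean value {vals[tuple(bad)]!r} at row "
            f"{pa_raw.index[bad[0]]!r}, column {pa_raw.columns[bad[1]]!r}"
        )
    pa = pa_raw.astype(bool)

    probes = pd.read_csv(probe_path, sep=_sep_for(Path(probe_path)), dtype={"probe_id": str})
    if "probe_id" not in probes.columns or "entrez_id" not in probes.columns:
        raise ValueError(f"probe file {probe_path}: need columns probe_id, entrez_id")
    probes["entrez_id"] = pd.array(
        pd.to_numeric(probes["entrez_id"], errors="raise"), dtype="Int64"
    )
    probes = probes.set_index("probe_id")

    samples = pd.read_csv(sample_path, sep=_sep_for(Path(sample_path)), dtype={"sample_id": str})
    missing = [c for c in ("sample_id", *_SAMPLE_COLUMNS) if c not in samples.columns]
    if missing:
        raise ValueError(f"sample file {sample_path}: missing columns {missing}")
    samples = samples.set_index("sample_id")
    donor_ids = samples["donor_id"].unique()
    if len(donor_ids) != 1:
        raise ValueError(f"sample file {sample_path}: expected one donor_id, got {list(donor_ids)}")

    return DonorBundle(
        donor_id=str(donor_ids[0]),
        expr=expr,
        pa=pa,
        probes=probes,
        samples=samples.drop(columns=["donor_id"]),
    )


def write_donor_bundle(bundle: DonorBundle, out_dir, fmt: str = "tsv") -> dict[str, Path]:
    """Write a bundle as four delimited text files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "," if fmt == "csv" else "\t"
    paths = {
        "expr": out_dir / f"expression.{fmt}",
        "pa": out_dir / f"pa_calls.{fmt}",
        "probes": out_dir / f"probes.{fmt}",
        "samples": out_dir / f"samples.{fmt}",
    }
    bundle.expr.rename_axis("probe_id").to_csv(paths["expr"], sep=sep)
    bundle.pa.astype(int).rename_axis("probe_id").to_csv(paths["pa"], sep=sep)
    bundle.probes.rename_axis("probe_id").to_csv(paths["probes"], sep=sep)
    samples = bundle.samples.copy()
    samples.insert(0, "donor_id", bundle.donor_id)
    samples.rename_axis("sample_id").to_csv(paths["samples"], sep=sep)
    return paths


def read_gene_sets_gmt(path, universe: Iterable[int], name: str | None = None) -> GeneSetCollection:
    """Read GMT lines (set_id TAB description TAB gene...) intersected with the universe.

    Sets that become empty after intersection are retained with size 0 so that
    callers can see (and report) them.
    """
    universe = frozenset(int(g) for g in universe)
    sets: dict[str, GeneSet] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            set_id, label = fields[0], fields[1]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {set_id!r}")
            genes = frozenset(int(g) for g in fields[2:] if g != "")
            sets[set_id] = GeneSet(label=label, genes=genes & universe)
    return GeneSetCollection(name=name or path.stem, sets=sets, universe=universe)


def write_gene_sets_gmt(coll: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for set_id, gs in coll.sets.items():
            genes = "\t".join(str(g) for g in sorted(gs.genes))
            fh.write(f"{set_id}\t{gs.label}\t{genes}\n" if genes else f"{set_id}\t{gs.label}\n")
    return path


def read_gene_disease_table(
    path,
    universe: Iterable[int],
    gene_col: str = "gene_id",
    disease_col: str = "disease_id",
    name_col: str = "disease_name",
) -> GeneSetCollection:
    """Read a gene-disease association table into one gene set per disease."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in (gene_col, disease_col, name_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    universe = frozenset(int(g) for g in universe)
    sets: dict[str, GeneSet] = {}
    for did, sub in df.groupby(disease_col, sort=True):
        genes = frozenset(int(g) for g in sub[gene_col]) & universe
        sets[str(did)] = GeneSet(label=str(sub[name_col].iloc[0]), genes=genes)
    return GeneSetCollection(name=path.stem, sets=sets, universe=universe)


def read_homology_table(path) -> HomologyMap:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return HomologyMap(pairs=df)


def write_homology_table(hom: HomologyMap, path) -> Path:
    path = Path(path)
    hom.pairs.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_network_masks(paths: Sequence, labels: Sequence[str]) -> NetworkAtlas:
    """Read binary NIfTI masks sharing one grid and affine into a NetworkAtlas."""
    import nibabel as nib

    if len(paths) != len(labels):
        raise ValueError("one label per mask file required")
    masks = []
    affine = None
    shape = None
    for p, lab in zip(paths, labels):
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj)
        if affine is None:
            affine, shape = img.affine, data.shape
        else:
            if data.shape != shape:
                raise ValueError(f"mask {p}: shape {data.shape} differs from {shape}")
            if not np.allclose(img.affine, affine, atol=1e-6):
                raise ValueError(f"mask {p}: affine differs from first mask")
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask {p}: non-binary mask (values {uniq[:5]})")
        masks.append(data.astype(bool))
    return NetworkAtlas(labels=list(labels), masks=np.stack(masks), affine=affine)


def write_network_masks(atlas: NetworkAtlas, out_dir) -> list[Path]:
    """Write each mask as an uncompressed .nii volume (deterministic bytes)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lab, mask in zip(atlas.labels, atlas.masks):
        img = nib.Nifti1Image(mask.astype(np.uint8), atlas.affine)
        p = out_dir / f"network_{lab}.nii"
        nib.save(img, str(p))
        paths.append(p)
    return paths
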