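"""Over-representation analysis of gene lists against gene-set collections.

The statistic is the upper-tail hypergeometric p of the overlap between a
gene list and a gene set within a fixed universe, with the unconditional
cross-product odds ratio of the 2x2 table, and Benjamini-Hochberg adjustment
across exactly the tested sets of one collection (sets below the family's
minimum in-universe size are excluded before testing).

Mouse cell-type marker sets are converted to human via a homology table;
human genes claimed by two or more distinct mouse source genes are ambiguous
and removed from every cell type before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSetCollection, HomologyMap

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerCollection",
    "map_markers_to_human",
    "hypergeom_enrich_p",
    "odds_ratio_2x2",
    "enrich_collection",
]


@dataclass
class MarkerCollection:
    """Human Entrez marker sets per cell type, with mouse provenance.

    ``provenance`` maps each retained human marker to its mouse source gene;
    ``collisions`` records human genes removed because two distinct mouse
    genes mapped onto them; ``unmapped`` records dropped mouse markers with
    no homology row.
    """

    cell_types: dict[str, frozenset]
    provenance: dict[int, int] = field(default_factory=dict)
    collisions: frozenset = frozenset()
    unmapped: frozenset = frozenset()

    def sizes(self) -> pd.Series:
        return pd.Series({ct: len(g) for ct, g in self.cell_types.items()}, dtype=int)

    def to_collection(self, universe: Iterable[int], name: str = "cell_types") -> GeneSetCollection:
        from .io import GeneSet

        universe = frozenset(int(g) for g in universe)
        sets = {
            ct: GeneSet(label=ct, genes=frozenset(g) & universe)
            for ct, g in self.cell_types.items()
        }
        return GeneSetCollection(name=name, sets=sets, universe=universe)


def map_markers_to_human(
    markers: Mapping[str, Iterable[int]],
    hom: HomologyMap,
    universe: Iterable[int],
) -> MarkerCollection:
    """Convert mouse marker sets to human homologs within the universe.

    Mouse markers with no homology row are dropped; any human gene targeted
    by two or more distinct mouse source genes (among the markers) is removed
    from every cell type; the result is intersected with the universe.
    """
    universe = frozenset(int(g) for g in universe)
    pair_lookup = hom.pairs.groupby("source_id")["target_id"].apply(list).to_dict()

    mapped: dict[str, set] = {}
    sources_of: dict[int, set] = {}
    unmapped: set = set()
    for ct, mouse_genes in markers.items():
        mapped[ct] = set()
        for mg in mouse_genes:
            targets = pair_lookup.get(int(mg))
            if not targets:
                unmapped.add(int(mg))
                continue
            for hg in targets:
                mapped[ct].add(int(hg))
                sources_of.setdefault(int(hg), set()).add(int(mg))

    collisions = {hg for hg, srcs in sources_of.items() if len(srcs) > 1}
    if unmapped:
        logger.info("markers without homologs dropped: %s", sorted(unmapped))
    if collisions:
        logger.info("ambiguous human genes removed from all cell types: %s", sorted(collisions))

    cell_types = {
        ct: frozenset(g for g in genes if g not in collisions and g in universe)
        for ct, genes in mapped.items()
    }
    provenance = {
        hg: next(iter(srcs))
        for hg, srcs in sources_of.items()
        if hg not in collisions and hg in universe
    }
    return MarkerCollection(
        cell_types=cell_types,
        provenance=provenance,
        collisions=frozenset(collisions),
        unmapped=frozenset(unmapped),
    )


def hypergeom_enrich_p(
    overlap: int, list_size: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeom(universe_size, set_size, list_size)."""
    overlap, list_size, set_size, universe_size = (
        int(overlap), int(list_size), int(set_size), int(universe_size)
    )
    if not (0 <= overlap <= min(list_size, set_size) <= universe_size):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, list={list_size}, "
            f"set={set_size}, universe={universe_size}"
        )
    if max(list_size, set_size) > universe_size:
        raise ValueError("set or list larger than universe")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, list_size))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Unconditional cross-product odds ratio (a*d)/(b*c) of a 2x2 table.

    a = overlap, b = set only, c = list only, d = neither.  Returns +inf when
    b*c == 0 with a*d > 0, and NaN when both products are zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    ad, bc = a * d, b * c
    if bc == 0:
        return float("inf") if ad > 0 else float("nan")
    return ad / bc


def enrich_collection(
    gene_list: Iterable[int],
    coll: GeneSetCollection,
    min_set: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in every testable set.

    Sets whose in-universe size is below ``min_set`` are excluded before
    testing; BH adjustment runs across exactly the tested sets.  The gene
    list must be a subset of the collection's universe.

    Returns one row per tested set, sorted by p ascending:
    set_id, label, set_size_in_universe, list_size, overlap, odds_ratio,
    p, p_bh, significant.
    """
    gene_list = frozenset(int(g) for g in gene_list)
    offenders = gene_list - coll.universe
    if offenders:
        raise ValueError(f"gene list not contained in universe: {sorted(offenders)[:10]}")
    N = len(coll.universe)
    n_list = len(gene_list)
    rows = []
    for set_id, gs in coll.sets.items():
        genes = gs.genes & coll.universe
        K = len(genes)
        if K < min_set:
            continue
        a = len(gene_list & genes)
        b = K - a
        c = n_list - a
        d = N - K - c
        rows.append(
            {
                "set_id": set_id,
                "label": gs.label,
                "set_size_in_universe": K,
                "list_size": n_list,
                "overlap": a,
                "odds_ratio": odds_ratio_2x2(a, b, c, d),
                "p": hypergeom_enrich_p(a, n_list, K, N),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id", "label", "set_size_in_universe", "list_size",
            "overlap", "odds_ratio", "p",
        ],
    )
    if len(out):
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_bh"] < alpha
        out = out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    else:
        out["p_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
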