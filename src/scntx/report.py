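"""Summary matrices and tables: per-donor Z-scoring, cell-type x network
mean-expression matrices, and up/down overlap tables between target networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .collapse import GeneMatrix
from .enrichment import MarkerCollection

__all__ = ["zscore_by_donor", "celltype_network_matrix", "overlap_table"]


def zscore_by_donor(gm: GeneMatrix) -> GeneMatrix:
    """Z-score each gene across one donor's samples (n-1 standard deviation).

    Constant genes become all-zero rows (their list is attached as
    ``expr.attrs["constant_genes"]``).  A donor with fewer than two samples
    is an error.
    """
    if gm.n_samples < 2:
        raise ValueError(f"donor {gm.donor_id}: Z-scoring needs at least 2 samples")
    vals = gm.expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(constant[:, None], 0.0, (vals - mean) / sd)
    expr = pd.DataFrame(z, index=gm.expr.index, columns=gm.expr.columns)
    expr.attrs["constant_genes"] = gm.expr.index[constant].tolist()
    return GeneMatrix(
        donor_id=gm.donor_id,
        expr=expr,
        samples=gm.samples,
        chosen_probe=gm.chosen_probe,
    )


def celltype_network_matrix(
    gms: Sequence[GeneMatrix],
    markers: MarkerCollection,
    assignment: pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean Z-scored expression per cell type per network.

    Averaging order is fixed: over a cell type's marker genes first, then
    over a network's samples within each donor, then over donors.  Cells with
    no markers present in the data or no contributing samples are NaN.

    Parameters expect gene matrices that are already Z-scored per donor.

    Returns (matrix, counts): cell_type x network mean values and the number
    of donor-sample observations behind each cell.
    """
    if labels is None:
        labels = sorted(assignment["network_label"].dropna().unique())
    cell_types = list(markers.cell_types)
    per_donor = np.full((len(gms), len(cell_types), len(labels)), np.nan)
    counts = np.zeros((len(cell_types), len(labels)), dtype=int)
    for di, gm in enumerate(gms):
        sub = assignment[assignment["donor_id"] == gm.donor_id]
        label_samples = {
            lab: [s for s in sub.loc[sub["network_label"] == lab, "sample_id"]
                  if s in gm.expr.columns]
            for lab in labels
        }
        for ci, ct in enumerate(cell_types):
            genes = [g for g in markers.cell_types[ct] if g in gm.expr.index]
            if not genes:
                continue
            marker_mean = gm.expr.loc[genes].mean(axis=0)  # over markers first
            for li, lab in enumerate(labels):
                sids = label_samples[lab]
                if not sids:
                    continue
                per_donor[di, ci, li] = marker_mean[sids].mean()  # then samples
                counts[ci, li] += len(sids)
    finite = np.isfinite(per_donor)
    n_donors = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):  # cells with no donors stay NaN
        mat = np.where(finite, per_donor, 0.0).sum(axis=0) / np.where(
            n_donors > 0, n_donors, np.nan
        )  # then donors
    matrix = pd.DataFrame(mat, index=cell_types, columns=list(labels))
    matrix.index.name = "cell_type"
    count_df = pd.DataFrame(counts, index=cell_types, columns=list(labels))
    count_df.index.name = "cell_type"
    return matrix, count_df


def overlap_table(
    up_a: Iterable,
    down_a: Iterable,
    up_b: Iterable,
    down_b: Iterable,
    labels: tuple[str, str] = ("C", "D"),
) -> pd.DataFrame:
    """Counts and memberships of up/down gene-list overlap between two networks."""
    a_lab, b_lab = labels
    rows = []
    for direction, la, lb in (("up", up_a, up_b), ("down", down_a, down_b)):
        sa, sb = set(la), set(lb)
        inter = sorted(sa & sb)
        rows.append(
            {
                "direction": direction,
                f"n_{a_lab}": len(sa),
                f"n_{b_lab}": len(sb),
                "n_overlap": len(inter),
                "overlap_genes": inter,
            }
        )
    return pd.DataFrame(rows).set_index("direction")
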