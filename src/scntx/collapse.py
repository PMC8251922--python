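"""Probe filtering and many-probes-to-one-gene collapsing.

Filtering removes probes with missing Entrez IDs and probes expressed above
background in fewer than a configurable fraction of all samples pooled across
donors (presence/absence flags).  Collapsing then keeps one probe per gene,
chosen once on the donor-concatenated data and applied identically to every
donor:

* 1 probe: that probe;
* 2 probes: the one with the larger sample variance (n-1 estimator);
* >=3 probes: the one with the highest connectivity, i.e. the largest sum of
  signed Pearson correlations with the gene's other probes.

Exact ties are broken by the lexicographically smallest probe_id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DonorBundle

__all__ = ["GeneMatrix", "filter_probes", "collapse_probes"]


@dataclass
class GeneMatrix:
    """One donor's gene x sample log2 expression after probe collapsing."""

    donor_id: str
    expr: pd.DataFrame  # index: int Entrez IDs; columns: sample_ids
    samples: pd.DataFrame
    chosen_probe: dict[int, str]

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError("duplicate gene IDs in GeneMatrix")
        if not self.expr.columns.equals(pd.Index(self.samples.index)):
            raise ValueError("sample annotation mismatch in GeneMatrix")

    @property
    def genes(self) -> list[int]:
        return self.expr.index.tolist()

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]


def _check_common_probes(bundles: Sequence[DonorBundle]) -> pd.Index:
    probes = bundles[0].expr.index
    for b in bundles[1:]:
        if not b.expr.index.equals(probes):
            raise ValueError(
                f"probe lists differ across donors ({bundles[0].donor_id} vs {b.donor_id})"
            )
    return probes


def filter_probes(
    bundles: Sequence[DonorBundle], pa_fraction: float = 0.01
) -> list[DonorBundle]:
    """Drop missing-Entrez probes and probes present in < pa_fraction of samples.

    The presence fraction is computed over all samples concatenated across
    donors; probes at exactly the threshold are retained.  The same probe set
    is removed from every donor.
    """
    if not 0.0 <= pa_fraction <= 1.0:
        raise ValueError("pa_fraction must be in [0, 1]")
    probes = _check_common_probes(bundles)
    pa_all = pd.concat([b.pa for b in bundles], axis=1)
    presence = pa_all.to_numpy().mean(axis=1)
    has_entrez = bundles[0].probes["entrez_id"].notna().to_numpy()
    keep = probes[(presence >= pa_fraction) & has_entrez]
    return [b.subset_probes(keep) for b in bundles]


def _choose_probe(probe_ids: list[str], X: np.ndarray) -> str:
    """Pick one probe for a gene from its probes' concatenated sample rows."""
    if len(probe_ids) == 1:
        return probe_ids[0]
    if len(probe_ids) == 2:
        score = X.var(axis=1, ddof=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)  # constant probes contribute 0
        np.fill_diagonal(corr, 0.0)
        score = corr.sum(axis=1)
    # max score, exact ties broken by smallest probe_id
    order = sorted(range(len(probe_ids)), key=lambda i: (-score[i], probe_ids[i]))
    return probe_ids[order[0]]


def collapse_probes(bundles: Sequence[DonorBundle]) -> list[GeneMatrix]:
    """Collapse filtered probes to one expression row per Entrez gene.

    Selection statistics use the donor-concatenated raw log2 values; the
    chosen probe is identical across donors.
    """
    _check_common_probes(bundles)
    probes = bundles[0].probes
    if probes["entrez_id"].isna().any():
        raise ValueError("collapse_probes requires filtered probes (missing Entrez present)")
    concat = pd.concat([b.expr for b in bundles], axis=1)
    concat_vals = concat.to_numpy()
    pos = {p: i for i, p in enumerate(concat.index)}

    chosen: dict[int, str] = {}
    for entrez, sub in probes.groupby("entrez_id", sort=True):
        pids = sorted(sub.index.tolist())
        X = concat_vals[[pos[p] for p in pids]]
        chosen[int(entrez)] = _choose_probe(pids, X)

    genes = sorted(chosen)
    probe_order = [chosen[g] for g in genes]
    out = []
    for b in bundles:
        expr = b.expr.loc[probe_order]
        expr.index = pd.Index(genes, name="entrez_id")
        out.append(
            GeneMatrix(
                donor_id=b.donor_id,
                expr=expr,
                samples=b.samples,
                chosen_probe=dict(chosen),
            )
        )
    return out
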