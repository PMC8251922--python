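"""Expression-weighted cell-type enrichment (EWCE).

A gene's specificity for a cell type is its mean linear-scale expression in
that cell type divided by its summed mean expression across all cell types.
The test asks whether a gene list's mean specificity for a cell type exceeds
that of random gene lists of the same size drawn uniformly (without
replacement) from the specificity matrix.  The bootstrap p uses the add-one
rule p = (1 + #{null >= observed}) / (1 + R), so p is never 0; when the
number of possible null lists C(n, |target|) is at most the requested number
of replicates, the null lists are enumerated exhaustively instead of sampled
(method="auto"), which bounds |p - exact| by 1/(#lists + 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["SpecificityMatrix", "specificity_matrix", "ewce_test"]


@dataclass
class SpecificityMatrix:
    """Gene x cell-type specificity in [0, 1]; rows sum to 1 unless flagged.

    ``flagged`` indexes genes whose total mean expression was 0 (all-zero
    specificity rows); these are excluded from testing.
    """

    spec: pd.DataFrame
    flagged: pd.Index

    @property
    def genes(self) -> pd.Index:
        return self.spec.index

    @property
    def cell_types(self) -> list[str]:
        return self.spec.columns.tolist()


def specificity_matrix(ct_expr: pd.DataFrame) -> SpecificityMatrix:
    """Row-normalize a gene x cell-type matrix of mean linear-scale expression.

    Input must be non-negative (de-log upstream if needed); all-zero genes
    are kept as all-zero rows and flagged.
    """
    vals = ct_expr.to_numpy(dtype=float)
    if np.any(vals < 0):
        g, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative expression at gene {ct_expr.index[g]!r}, "
            f"cell type {ct_expr.columns[c]!r}"
        )
    totals = vals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(totals[:, None] > 0, vals / totals[:, None], 0.0)
    flagged = ct_expr.index[totals == 0]
    if len(flagged):
        logger.info("specificity_matrix: %d all-zero gene(s) flagged", len(flagged))
    return SpecificityMatrix(
        spec=pd.DataFrame(spec, index=ct_expr.index, columns=ct_expr.columns),
        flagged=flagged,
    )


def _null_means_exhaustive(S: np.ndarray, t: int) -> np.ndarray:
    n = S.shape[0]
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), t)),
        dtype=np.intp,
    ).reshape(-1, t)
    return S[idx].mean(axis=1)


def _null_means_bootstrap(
    S: np.ndarray, t: int, reps: int, rng: np.random.Generator, chunk: int = 1000
) -> np.ndarray:
    n = S.shape[0]
    out = []
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        # uniform without-replacement draws via random-key argpartition
        keys = rng.random((m, n))
        idx = np.argpartition(keys, t - 1, axis=1)[:, :t]
        out.append(S[idx].mean(axis=1))
        done += m
    return np.concatenate(out, axis=0)


def ewce_test(
    target: Iterable,
    spec: SpecificityMatrix,
    reps: int = 10000,
    seed: int | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Bootstrap test of mean cell-type specificity of a gene list.

    Parameters
    ----------
    target : gene IDs, all present in the specificity matrix.  Flagged
        (all-zero) genes are excluded from both the target and the null pool.
    reps : requested number of null lists.
    seed : RNG seed; identical calls with the same seed are bit-identical.
    method : {"auto", "bootstrap", "exhaustive"}.  "auto" enumerates all
        C(n, |target|) lists when that count is <= reps.

    Returns a DataFrame (cell_type, observed, boot_mean, boot_sd, fold, p,
    p_bh) with ``attrs["reps"]`` holding the effective number of null lists
    and ``attrs["method"]`` the method used.
    """
    target = list(dict.fromkeys(target))
    missing = [g for g in target if g not in spec.spec.index]
    if missing:
        raise ValueError(f"target genes absent from specificity matrix: {missing[:10]}")
    flagged = set(spec.flagged)
    kept = [g for g in target if g not in flagged]
    if len(kept) < len(target):
        logger.warning("ewce_test: %d flagged target gene(s) excluded", len(target) - len(kept))
    if not kept:
        raise ValueError("empty target list after removing flagged genes")
    pool = spec.spec.drop(index=spec.flagged, errors="ignore")
    S = pool.to_numpy(dtype=float)
    t = len(kept)
    n = S.shape[0]
    observed = pool.loc[kept].to_numpy().mean(axis=0)

    n_lists = comb(n, t)
    if method == "auto":
        method = "exhaustive" if n_lists <= reps else "bootstrap"
    if method == "exhaustive":
        null_means = _null_means_exhaustive(S, t)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        null_means = _null_means_bootstrap(S, t, reps, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    R = null_means.shape[0]

    exceed = (null_means >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + R)
    boot_mean = null_means.mean(axis=0)
    boot_sd = null_means.std(axis=0, ddof=1) if R > 1 else np.zeros_like(boot_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(boot_mean > 0, observed / boot_mean, np.nan)

    out = pd.DataFrame(
        {
            "cell_type": pool.columns,
            "observed": observed,
            "boot_mean": boot_mean,
            "boot_sd": boot_sd,
            "fold": fold,
            "p": p,
        }
    )
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out.attrs["reps"] = int(R)
    out.attrs["method"] = method
    return out
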