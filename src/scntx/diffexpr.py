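"""Donor-level differential expression and random-effects meta-analysis.

Per donor, each gene's expression in a target network is compared with the
pooled comparison networks by a two-tailed Welch t test; the mean difference
of log2 values is the log2 fold-change and its sampling variance is
s1^2/n1 + s2^2/n2 (raw mean difference).  Donor effects are then combined by
a DerSimonian-Laird random-effects meta-analysis: the moment estimator

    tau^2 = max(0, (Q - (k - 1)) / C),   C = sum(w) - sum(w^2)/sum(w)

with fixed-effect weights w_i = 1/v_i, random-effects weights
w*_i = 1/(v_i + tau^2), inverse-variance-weighted summary effect, and a
z (default) or donor-level one-sample t summary test.  Genes are called
differentially expressed when |summary FC| exceeds a threshold (strict) and
the Benjamini-Hochberg adjusted p falls below alpha (strict).

Differential stability measures cross-donor reproducibility: per gene, the
mean Pearson correlation of structure-averaged expression profiles over all
donor pairs.
"""

from __future__ import annotations

import itertools
import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .collapse import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "welch_test",
    "donor_de",
    "dl_meta",
    "meta_analyze",
    "bh_adjust",
    "call_de",
    "differential_stability",
]


def welch_test(mean1, var1, n1, mean2, var2, n2):
    """Welch unequal-variance t test from group summaries (vectorized).

    Returns (fc, var, t, df, p) where fc = mean1 - mean2 and
    var = var1/n1 + var2/n2.  Where var == 0 the t, df and p are NaN.
    """
    mean1, var1, mean2, var2 = (np.asarray(a, dtype=float) for a in (mean1, var1, mean2, var2))
    fc = mean1 - mean2
    a, b = var1 / n1, var2 / n2
    var = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / np.sqrt(var)
        df = var**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = ~(var > 0)
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    p = np.where(bad, np.nan, p)
    return fc, var, t, df, p


def donor_de(
    gm: GeneMatrix,
    assignment: pd.DataFrame,
    target: str,
    comparison: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Welch t test of one donor's target network vs pooled comparison.

    Samples assigned to no network (or to networks outside target+comparison)
    are excluded.  Returns an empty frame (with a log message) when either
    group has fewer than two samples.  Genes with zero variance in both
    groups are marked invalid (valid=False) and carry no p-value.
    """
    comparison = list(comparison)
    if target in comparison:
        raise ValueError(f"target {target!r} must not be in the comparison list")
    sub = assignment[assignment["donor_id"] == gm.donor_id]
    in_ids = sub.loc[sub["network_label"] == target, "sample_id"]
    out_ids = sub.loc[sub["network_label"].isin(comparison), "sample_id"]
    in_ids = [s for s in in_ids if s in gm.expr.columns]
    out_ids = [s for s in out_ids if s in gm.expr.columns]
    n_in, n_out = len(in_ids), len(out_ids)
    cols = ["gene", "donor_id", "fc", "var", "n_in", "n_out", "t", "df", "p_donor", "valid"]
    if n_in < 2 or n_out < 2:
        logger.warning(
            "donor %s: too few samples for %s vs %s (n_in=%d, n_out=%d); skipped",
            gm.donor_id, target, comparison, n_in, n_out,
        )
        return pd.DataFrame(columns=cols)
    X_in = gm.expr[in_ids].to_numpy()
    X_out = gm.expr[out_ids].to_numpy()
    fc, var, t, df, p = welch_test(
        X_in.mean(axis=1), X_in.var(axis=1, ddof=1), n_in,
        X_out.mean(axis=1), X_out.var(axis=1, ddof=1), n_out,
    )
    return pd.DataFrame(
        {
            "gene": gm.expr.index.to_numpy(),
            "donor_id": gm.donor_id,
            "fc": fc,
            "var": var,
            "n_in": n_in,
            "n_out": n_out,
            "t": t,
            "df": df,
            "p_donor": p,
            "valid": var > 0,
        }
    )


class DLResult(NamedTuple):
    k: int
    fc_summary: float
    se_summary: float
    tau2: float
    p: float


def dl_meta(y, v, summary_test: str = "z") -> DLResult:
    """DerSimonian-Laird combination of one gene's donor effects.

    Parameters
    ----------
    y, v : per-donor effects and their sampling variances.  Donors with
        v <= 0 are excluded with a warning.
    summary_test : {"z", "donor-t"}
        "z": two-sided normal test of fc_summary / se_summary.
        "donor-t": one-sample t of the k donor effects against 0 (df = k-1).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = v > 0
    if not ok.all():
        logger.warning("dl_meta: excluding %d donor(s) with non-positive variance", (~ok).sum())
    y, v = y[ok], v[ok]
    k = len(y)
    if k == 0:
        raise ValueError("dl_meta: no valid donor effects")
    if k == 1:
        fc, tau2, se = float(y[0]), 0.0, float(np.sqrt(v[0]))
    else:
        w = 1.0 / v
        fe = np.sum(w * y) / np.sum(w)
        Q = float(np.sum(w * (y - fe) ** 2))
        C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / C)
        ws = 1.0 / (v + tau2)
        fc = float(np.sum(ws * y) / np.sum(ws))
        se = float(np.sum(ws) ** -0.5)
    if summary_test == "z":
        p = float(2.0 * stats.norm.sf(abs(fc / se))) if se > 0 else float(fc == 0)
    elif summary_test == "donor-t":
        p = float(stats.ttest_1samp(y, 0.0).pvalue) if k >= 2 else np.nan
    else:
        raise ValueError(f"unknown summary_test {summary_test!r}")
    return DLResult(k=k, fc_summary=fc, se_summary=se, tau2=tau2, p=p)


def meta_analyze(effects: pd.DataFrame, summary_test: str = "z") -> pd.DataFrame:
    """Vectorized DL meta-analysis over all genes of a long donor-effect table.

    ``effects`` is the concatenation of :func:`donor_de` outputs over donors.
    Invalid donor records (valid=False or var <= 0) are excluded per gene;
    genes with no valid record are absent from the output.  Single-donor
    genes are kept with tau2 = 0 and flagged via the k column.
    """
    eff = effects[effects["valid"] & (effects["var"] > 0)]
    if eff.empty:
        return pd.DataFrame(columns=["gene", "k", "fc_summary", "se_summary", "tau2", "p"])
    Y = eff.pivot(index="gene", columns="donor_id", values="fc")
    V = eff.pivot(index="gene", columns="donor_id", values="var")
    y = Y.to_numpy()
    v = V.to_numpy()
    m = np.isfinite(y) & np.isfinite(v) & (v > 0)
    y = np.where(m, y, np.nan)
    v = np.where(m, v, np.nan)
    k = m.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(m, 1.0 / v, 0.0)
        sw = w.sum(axis=1)
        fe = np.nansum(w * y, axis=1) / sw
        Q = np.nansum(w * (y - fe[:, None]) ** 2, axis=1)
        C = sw - (w**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (Q - (k - 1)) / C)
        tau2 = np.where(k >= 2, tau2, 0.0)
        ws = np.where(m, 1.0 / (v + tau2[:, None]), 0.0)
        fc = np.nansum(ws * y, axis=1) / ws.sum(axis=1)
        se = ws.sum(axis=1) ** -0.5

    if summary_test == "z":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(fc / se))
    elif summary_test == "donor-t":
        mean = np.nanmean(y, axis=1)
        sd = np.nanstd(y, axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = mean / (sd / np.sqrt(k))
            p = 2.0 * stats.t.sf(np.abs(tstat), k - 1)
        p = np.where(k >= 2, p, np.nan)
    else:
        raise ValueError(f"unknown summary_test {summary_test!r}")

    return pd.DataFrame(
        {
            "gene": Y.index.to_numpy(),
            "k": k.astype(int),
            "fc_summary": fc,
            "se_summary": se,
            "tau2": tau2,
            "p": p,
        }
    ).reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(
    meta: pd.DataFrame, fc_thresh: float = 1.0, alpha: float = 0.05
) -> tuple[list, list]:
    """Split genes into up-/down-regulated calls at strict thresholds.

    up: fc_summary > fc_thresh and p_bh < alpha;
    down: fc_summary < -fc_thresh and p_bh < alpha.
    """
    if fc_thresh <= 0:
        raise ValueError("fc_thresh must be positive")
    if "p_bh" not in meta.columns:
        raise ValueError("call_de requires a p_bh column (run bh_adjust first)")
    sig = meta["p_bh"] < alpha
    up = meta.loc[sig & (meta["fc_summary"] > fc_thresh), "gene"].tolist()
    down = meta.loc[sig & (meta["fc_summary"] < -fc_thresh), "gene"].tolist()
    return sorted(up), sorted(down)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows; NaN where either row is constant."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def differential_stability(
    gms: Sequence[GeneMatrix], min_shared: int = 3
) -> pd.DataFrame:
    """Per-gene mean Pearson correlation of regional profiles over donor pairs.

    Expression is averaged per structure_acronym within each donor; each
    donor pair contributes the per-gene correlation across structures present
    in both donors (the pair is skipped for a gene when shared structures
    < min_shared or either profile is constant).  Deciles rank the ds values
    over all scored genes (10 = most stable).
    """
    if len(gms) < 2:
        raise ValueError("differential stability needs at least two donors")
    genes = gms[0].expr.index
    for gm in gms[1:]:
        if not gm.expr.index.equals(genes):
            raise ValueError("gene matrices must share an identical gene index")
    profiles = []
    for gm in gms:
        prof = gm.expr.T.groupby(gm.samples["structure_acronym"]).mean().T
        profiles.append(prof)

    corrs = []
    for a, b in itertools.combinations(range(len(gms)), 2):
        shared = profiles[a].columns.intersection(profiles[b].columns)
        if len(shared) < min_shared:
            continue
        corrs.append(
            _rowwise_pearson(
                profiles[a][shared].to_numpy(), profiles[b][shared].to_numpy()
            )
        )
    if not corrs:
        return pd.DataFrame({"gene": genes, "ds": np.nan, "n_pairs_used": 0, "decile": pd.NA})
    R = np.column_stack(corrs)
    finite = np.isfinite(R)
    n_used = finite.sum(axis=1)
    sums = np.where(finite, R, 0.0).sum(axis=1)
    ds = np.where(n_used > 0, sums / np.maximum(n_used, 1), np.nan)
    out = pd.DataFrame({"gene": genes.to_numpy(), "ds": ds, "n_pairs_used": n_used})
    scored = out["ds"].notna()
    decile = pd.Series(pd.NA, index=out.index, dtype="Int64")
    if scored.sum() > 0:
        ranks = out.loc[scored, "ds"].rank(method="first")
        decile.loc[scored] = np.ceil(ranks / scored.sum() * 10).astype(int).clip(1, 10)
    out["decile"] = decile
    return out
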