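"""Richness and evenness estimation on SRS-normalized counts.

Chao1 (bias-corrected by default) estimates richness from singleton and
doubleton counts; Pielou's J is Shannon entropy over ln(observed richness).
Because both are sensitive to library size, estimation is intended for
SRS-normalized matrices whose columns share a common total -- this is
asserted, and non-integer abundances are rejected with a pointer to SRS.

The depth-layer comparison is a one-way ANOVA of richness on depth layer
with Tukey HSD pairwise contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from stratiscope.io_model import StratiscopeError
from stratiscope.normalize import TransformedMatrix

logger = logging.getLogger(__name__)

SUBSET_TAGS = ("all", "CAZyme", "TP", "PEP")


def chao1(abundances, bias_corrected: bool = True) -> dict:
    """Chao1 richness estimate from one sample's abundance vector.

    Bias-corrected form: S_obs + F1(F1-1) / (2(F2+1)); the classic form
    S_obs + F1^2/(2 F2) is available but undefined when F2 = 0.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size and not np.array_equal(a, np.floor(a)):
        raise StratiscopeError(
            "Chao1 requires integer abundances; run SRS normalization first"
        )
    a = a[a > 0]
    s_obs = int(a.size)
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    if bias_corrected:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        if f2 == 0:
            raise StratiscopeError("classic Chao1 undefined with no doubletons")
        est = s_obs + f1 * f1 / (2.0 * f2)
    return {"observed_richness": s_obs, "chao1": est, "f1": f1, "f2": f2}


def pielou(abundances) -> float:
    """Pielou's evenness J = H / ln(S_obs); NaN when S_obs < 2."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size < 2:
        return float("nan")
    p = a / a.sum()
    h = -(p * np.log(p)).sum()
    return float(h / math.log(a.size))


@dataclass
class GroupComparison:
    """One-way ANOVA of a diversity metric on depth layer, plus Tukey HSD."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    group_means: pd.Series


def diversity_table(
    srs: TransformedMatrix, subset_tag: str = "all", bias_corrected: bool = True
) -> pd.DataFrame:
    """Per-sample richness/evenness table from an SRS-normalized matrix."""
    if srs.transform_tag != "srs":
        raise StratiscopeError("diversity estimation expects an SRS-normalized matrix")
    totals = srs.values.sum(axis=0)
    if totals.nunique() != 1:
        raise StratiscopeError("SRS columns do not share a common total")
    rows = []
    for sample in srs.sample_ids:
        vec = srs.values[sample].to_numpy()
        est = chao1(vec, bias_corrected=bias_corrected)
        rows.append(
            {
                "sample_id": sample,
                "subset_tag": subset_tag,
                **est,
                "pielou_j": pielou(vec),
            }
        )
    return pd.DataFrame(rows)


def richness_anova(
    estimates: pd.DataFrame, metadata: pd.DataFrame, metric: str = "chao1"
) -> GroupComparison:
    """Compare a diversity metric between depth layers (ANOVA + Tukey HSD).

    Depth layers with a single sample are excluded with a warning (no
    within-group variance).
    """
    df = estimates.merge(
        metadata[["sample_id", "depth_m"]].reset_index(drop=True),
        on="sample_id", how="left",
    )
    if df["depth_m"].isna().any():
        bad = df.loc[df["depth_m"].isna(), "sample_id"].iloc[0]
        raise StratiscopeError(f"sample {bad!r} missing from metadata")
    sizes = df.groupby("depth_m").size()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        logger.warning("excluding depth layer(s) with one sample: %s", list(singletons))
        df = df[~df["depth_m"].isin(singletons)]
    groups = [g[metric].to_numpy(dtype=float) for _, g in df.groupby("depth_m")]
    if len(groups) < 2:
        raise StratiscopeError("need at least 2 depth layers with >= 2 samples")
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        # degenerate all-equal case: no variance anywhere
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
        if math.isnan(f_stat):  # zero within-group variance, groups differ
            f_stat, p = math.inf, 0.0
    tk = pairwise_tukeyhsd(
        df[metric].to_numpy(dtype=float), df["depth_m"].astype(str).to_numpy()
    )
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return GroupComparison(
        f_statistic=float(f_stat),
        df_between=len(groups) - 1,
        df_within=len(flat) - len(groups),
        p_value=float(p),
        pairwise=pairwise,
        group_means=df.groupby("depth_m")[metric].mean(),
    )
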