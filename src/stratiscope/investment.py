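"""Taxon-resolved transcription shares, gene-system investment log ratios,
and thaumarchaeal marker-gene ratios.

Relative metatranscriptomic data cannot say whether a gene system's absolute
transcription changes, but the *ratio* between two systems within one taxon
is invariant to the taxon's overall activity and to library size.  The
investment log ratio of systems A and B for a taxon is therefore computed
per biological replicate as log2(sum TPM of A-ORFs / sum TPM of B-ORFs),
then summarized as mean +/- SD over replicates for each depth x month.

Marker-gene analysis follows the same logic with radA (single-copy,
constitutive) as the per-genome reference: log2(amoA/radA) and
log2(hcd/radA) track ammonia-oxidation and carbon-fixation transcription
per cell.  Marker relative abundances are reported as percentages of total
transcripts (raw-count basis), as is taxon relative transcription.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from stratiscope.io_model import CountMatrix, StratiscopeError
from stratiscope.normalize import TransformedMatrix

logger = logging.getLogger(__name__)

RATIO_TYPES = {
    "CAZyme/PEP": ("CAZyme", "PEP"),
    "CAZyme/TP": ("CAZyme", "TP"),
    "PEP/TP": ("PEP", "TP"),
}

COMMUNITY = "(community)"


def taxon_relative_transcription(
    cm: CountMatrix, taxonomy: pd.DataFrame, rank: str = "order"
) -> pd.DataFrame:
    """Percent of total transcripts per taxon per sample (raw-count basis).

    ``rank="phylum"`` applies the usual presentation rule of splitting
    Proteobacteria to class level.
    """
    if rank not in ("phylum", "order"):
        raise StratiscopeError("rank must be 'phylum' or 'order'")
    tax = taxonomy.loc[cm.orf_ids]
    if rank == "phylum":
        labels = np.where(
            tax["phylum"] == "Proteobacteria", tax["class"], tax["phylum"]
        )
    else:
        labels = tax[rank].to_numpy()
    totals = cm.counts.sum(axis=0)
    grouped = cm.counts.groupby(pd.Series(labels, index=cm.counts.index)).sum()
    pct = grouped / totals * 100.0
    out = pct.reset_index(names="taxon").melt(
        id_vars="taxon", var_name="sample_id", value_name="percent"
    )
    return out


def system_totals(
    tpm: TransformedMatrix,
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "order",
) -> pd.DataFrame:
    """Sum member-ORF TPM per (taxon, sample, gene system).

    An ORF contributes to every system it is assigned to (a transporter may
    also be the marker amt); marker systems are kept per gene as
    ``marker:<name>``.  Rows with zero TPM are retained so that downstream
    ratios can flag them.  A ``total`` system row carries the taxon's whole
    TPM sum.
    """
    unknown = set(assignments["orf_id"]) - set(tpm.orf_ids)
    if unknown:
        raise StratiscopeError(
            f"assignment references unknown ORF(s), e.g. {sorted(unknown)[:3]}"
        )
    tax = taxonomy.loc[tpm.orf_ids]
    taxon_of = tax[rank] if rank in tax.columns else tax["order"]
    vals = tpm.values

    frames = []
    # per-system sums over assigned ORFs
    asg = assignments.copy()
    asg["system_key"] = np.where(
        asg["system"] == "marker", "marker:" + asg["family"], asg["system"]
    )
    for system_key, grp in asg.groupby("system_key"):
        member = vals.loc[vals.index.isin(set(grp["orf_id"]))]
        sums = member.groupby(taxon_of.loc[member.index]).sum()
        frames.append(_melt_totals(sums, system_key))
    # taxon totals over all ORFs
    frames.append(_melt_totals(vals.groupby(taxon_of).sum(), "total"))
    out = pd.concat(frames, ignore_index=True)

    # retain explicit zero rows for taxa lacking a system entirely
    taxa = out.loc[out["system"] == "total", "taxon"].unique()
    systems = out["system"].unique()
    full = pd.MultiIndex.from_product(
        [taxa, tpm.sample_ids, systems], names=["taxon", "sample_id", "system"]
    ).to_frame(index=False)
    out = full.merge(out, how="left").fillna({"tpm_sum": 0.0})
    return out


def _melt_totals(sums: pd.DataFrame, system: str) -> pd.DataFrame:
    m = sums.reset_index(names="taxon").melt(
        id_vars="taxon", var_name="sample_id", value_name="tpm_sum"
    )
    m.insert(1, "system", system)
    return m


def _community_totals(totals: pd.DataFrame) -> pd.DataFrame:
    comm = (
        totals.groupby(["sample_id", "system"], as_index=False)["tpm_sum"].sum()
    )
    comm.insert(0, "taxon", COMMUNITY)
    return comm


def investment_log_ratios(
    totals: pd.DataFrame,
    metadata: pd.DataFrame,
    log_base: float = 2.0,
    include_community: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD investment log ratios per taxon x depth x month.

    The ratio is computed per replicate, then averaged (never a ratio of
    means).  A zero numerator or denominator sum is replaced by half the
    smallest positive system TPM sum in the table (``pseudocount_used``
    flags it); replicates where both sums are zero are excluded and
    counted in ``n_excluded``.
    """
    if include_community:
        totals = pd.concat(
            [totals, _community_totals(totals)], ignore_index=True
        )
    wide = totals.pivot_table(
        index=["taxon", "sample_id"], columns="system", values="tpm_sum",
        fill_value=0.0, aggfunc="sum",
    )
    meta = metadata.set_index("sample_id") if metadata.index.name != "sample_id" \
        else metadata
    positive = totals.loc[
        totals["system"].isin({a for pair in RATIO_TYPES.values() for a in pair})
        & (totals["tpm_sum"] > 0), "tpm_sum"
    ]
    pseudo = positive.min() / 2.0 if len(positive) else np.nan
    log_div = np.log(log_base)

    rows = []
    wide = wide.reset_index()
    wide["depth_m"] = meta.loc[wide["sample_id"], "depth_m"].to_numpy()
    wide["month"] = meta.loc[wide["sample_id"], "month"].to_numpy()
    for (taxon, depth, month), grp in wide.groupby(["taxon", "depth_m", "month"]):
        for ratio_type, (sys_a, sys_b) in RATIO_TYPES.items():
            if sys_a not in grp.columns or sys_b not in grp.columns:
                continue
            ratios, used_pseudo, excluded = [], False, 0
            for _, rep in grp.iterrows():
                a, b = float(rep[sys_a]), float(rep[sys_b])
                if a == 0.0 and b == 0.0:
                    excluded += 1
                    continue
                if a == 0.0 or b == 0.0:
                    used_pseudo = True
                    a = a or pseudo
                    b = b or pseudo
                ratios.append(np.log(a / b) / log_div)
            if not ratios:
                logger.info("ratio %s undefined for %s at %s m %s",
                            ratio_type, taxon, depth, month)
                continue
            rows.append(
                {
                    "taxon": taxon,
                    "depth_m": depth,
                    "month": month,
                    "ratio_type": ratio_type,
                    "mean_log_ratio": float(np.mean(ratios)),
                    "sd_log_ratio": float(np.std(ratios, ddof=1))
                    if len(ratios) > 1 else 0.0,
                    "n_replicates": len(ratios),
                    "n_excluded": excluded,
                    "pseudocount_used": used_pseudo,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marker genes
# ---------------------------------------------------------------------------

def marker_relative_abundance(
    cm: CountMatrix, assignments: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Marker transcripts as a percentage of total transcripts.

    Per-sample percentages (raw-count basis) are averaged over replicates
    with SD, per marker x depth x month.
    """
    markers = assignments.loc[assignments["system"] == "marker"]
    totals = cm.counts.sum(axis=0)
    meta = metadata.set_index("sample_id") if metadata.index.name != "sample_id" \
        else metadata
    rows = []
    for marker, grp in markers.groupby("family"):
        member = cm.counts.loc[cm.counts.index.isin(set(grp["orf_id"]))]
        pct = member.sum(axis=0) / totals * 100.0
        df = pd.DataFrame(
            {
                "marker": marker,
                "sample_id": pct.index,
                "percent": pct.to_numpy(),
                "depth_m": meta.loc[pct.index, "depth_m"].to_numpy(),
                "month": meta.loc[pct.index, "month"].to_numpy(),
            }
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["marker", "sample_id", "percent", "depth_m", "month"]
        )
    return pd.concat(rows, ignore_index=True)


def marker_log_ratios(
    marker_abundance: pd.DataFrame,
    reference: str = "radA",
    numerators=("amoA", "hcd"),
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-replicate log ratios of marker abundance to the radA reference.

    radA must be present (it anchors per-genome transcription); replicates
    with zero radA fall back to a half-minimum pseudocount and are flagged.
    """
    if reference not in set(marker_abundance["marker"]):
        raise StratiscopeError(f"reference marker {reference!r} absent from data")
    wide = marker_abundance.pivot_table(
        index=["sample_id", "depth_m", "month"], columns="marker",
        values="percent", fill_value=0.0,
    ).reset_index()
    positive = marker_abundance.loc[marker_abundance["percent"] > 0, "percent"]
    pseudo = positive.min() / 2.0 if len(positive) else np.nan
    log_div = np.log(log_base)
    rows = []
    for (depth, month), grp in wide.groupby(["depth_m", "month"]):
        for marker in numerators:
            if marker not in grp.columns:
                continue
            ratios, used_pseudo = [], False
            for _, rep in grp.iterrows():
                num, den = float(rep[marker]), float(rep[reference])
                if num == 0.0 and den == 0.0:
                    continue
                if num == 0.0 or den == 0.0:
                    used_pseudo = True
                    num = num or pseudo
                    den = den or pseudo
                ratios.append(np.log(num / den) / log_div)
            if not ratios:
                continue
            rows.append(
                {
                    "depth_m": depth,
                    "month": month,
                    "numerator": marker,
                    "mean_log_ratio": float(np.mean(ratios)),
                    "sd_log_ratio": float(np.std(ratios, ddof=1))
                    if len(ratios) > 1 else 0.0,
                    "n_replicates": len(ratios),
                    "pseudocount_used": used_pseudo,
                }
            )
    return pd.DataFrame(rows)
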