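"""Resolve raw multi-tool prediction tables into per-ORF functional labels.

Four gene systems are handled:

* **CAZymes** -- a three-tool consensus (alignment/DIAMOND-style,
  profile/HMMER-style, peptide-pattern/Hotpep-style).  Single-tool calls are
  dropped below tool-specific quality thresholds (identity < 50 %, coverage
  < 0.5, hits < 10; metrics exactly at a threshold are retained).
  Multi-tool ORFs are ranked per candidate family by the number of tools
  voting for it, then by a normalized quality score summed over supporting
  tools; exact ties break lexicographically by family label.
* **Peptidases** -- Pfam profile hits mapped to MEROPS families; the
  highest-scoring hit wins per ORF, unmapped accessions go to a side report.
* **Transporters** -- TCDB family per ORF (argmax bit score) after applying
  profile-level overrides; the shipped defaults correct the two Pfam domains
  whose database mapping is known to be wrong (PF00909 -> Amt ammonium
  channel TC 1.A.11, PF00654 -> ClC chloride channel TC 2.A.49).
* **Marker genes** -- radA/amoA/hcd/amt hits gated on the profile database's
  recommended gathering score; hcd labels come from an upstream phylogenetic
  placement and pass through as given.

An ORF may carry labels in several systems (e.g. transporter and marker
amt) but never more than one CAZyme family.
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from stratiscope.io_model import StratiscopeError

logger = logging.getLogger(__name__)

TOOLS = ("alignment", "profile", "pattern")

#: metric column owned by each tool
TOOL_METRICS = {
    "alignment": ("percent_identity",),
    "profile": ("coverage",),
    "pattern": ("hits", "frequency"),
}

#: single-tool exclusion thresholds (strict "<" excludes; boundary retained)
MIN_IDENTITY = 50.0
MIN_COVERAGE = 0.5
MIN_HITS = 10

#: cap used to normalize pattern-tool hit counts into [0, 1]
HITS_CAP = 100

MARKERS = ("radA", "amoA", "hcd", "amt")

TC_NUMBER_RE = re.compile(r"^\d+\.[A-Z]\.\d+(\.\d+)*$")

#: default transporter overrides: profile -> (family, TC number)
DEFAULT_TC_OVERRIDES = {
    "PF00909": ("The Ammonium Channel Transporter (Amt) Family", "1.A.11"),
    "PF00654": ("The Chloride Carrier/Channel (ClC) Family", "2.A.49"),
}

ASSIGNMENT_COLUMNS = ["orf_id", "system", "family", "provenance"]


def _assignment_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


# ---------------------------------------------------------------------------
# CAZyme consensus
# ---------------------------------------------------------------------------

def _check_prediction_record(row) -> None:
    tool = row["tool"]
    if tool not in TOOLS:
        raise StratiscopeError(f"unknown tool label {tool!r} for ORF {row['orf_id']!r}")
    if not isinstance(row["family"], str) or not row["family"]:
        raise StratiscopeError(f"empty family label for ORF {row['orf_id']!r}")
    owned = set(TOOL_METRICS[tool])
    all_metrics = {"percent_identity", "coverage", "hits", "frequency"}
    for m in owned:
        if pd.isna(row[m]):
            raise StratiscopeError(
                f"{tool} record for ORF {row['orf_id']!r} lacks its metric {m!r}"
            )
    for m in all_metrics - owned:
        if not pd.isna(row[m]):
            raise StratiscopeError(
                f"{tool} record for ORF {row['orf_id']!r} carries foreign metric {m!r}"
            )


def _single_tool_passes(tool: str, row) -> bool:
    if tool == "alignment":
        return row["percent_identity"] >= MIN_IDENTITY
    if tool == "profile":
        return row["coverage"] >= MIN_COVERAGE
    return row["hits"] >= MIN_HITS


def _quality_score(tool: str, row, max_freq: float, hits_cap: int) -> float:
    """Per-tool quality normalized into [0, 1].

    Alignment: identity/100.  Profile: coverage.  Pattern: min(1, hits/cap)
    scaled by the hit frequency relative to the ORF's largest frequency.
    """
    if tool == "alignment":
        return float(row["percent_identity"]) / 100.0
    if tool == "profile":
        return float(row["coverage"])
    rel_freq = float(row["frequency"]) / max_freq if max_freq > 0 else 1.0
    return min(1.0, float(row["hits"]) / hits_cap) * rel_freq


def consensus_cazyme(
    predictions: pd.DataFrame, hits_cap: int = HITS_CAP
) -> pd.DataFrame:
    """Resolve raw CAZyme predictions to at most one family per ORF.

    Parameters
    ----------
    predictions
        One row per (ORF, tool) with columns ``orf_id``, ``tool``,
        ``family``, ``percent_identity``, ``coverage``, ``hits``,
        ``frequency`` (tool-foreign metrics NaN).
    hits_cap
        Hit count at which the pattern tool's quality saturates.

    Returns
    -------
    DataFrame with columns ``orf_id``, ``system`` (= ``"CAZyme"``),
    ``family``, ``provenance``.
    """
    if predictions.empty:
        return _assignment_frame([])
    for _, row in predictions.iterrows():
        _check_prediction_record(row)

    out = []
    for orf_id, grp in predictions.groupby("orf_id", sort=False):
        tools = grp["tool"].unique()
        if len(grp) == 1:
            row = grp.iloc[0]
            if _single_tool_passes(row["tool"], row):
                out.append((orf_id, "CAZyme", row["family"],
                            f"single-tool:{row['tool']}"))
            continue
        # >= 2 records: rank candidate families by (votes, summed quality)
        max_freq = float(grp.loc[grp["tool"] == "pattern", "frequency"].max()) \
            if (grp["tool"] == "pattern").any() else 0.0
        scores: dict[str, list] = {}
        for _, row in grp.iterrows():
            fam = row["family"]
            q = _quality_score(row["tool"], row, max_freq, hits_cap)
            votes, qual = scores.get(fam, (0, 0.0))
            scores[fam] = (votes + 1, qual + q)
        ranked = sorted(
            scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0])
        )
        best_fam, (votes, qual) = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == (votes, qual):
            logger.info(
                "consensus tie for ORF %s broken lexicographically: %s",
                orf_id, [f for f, s in ranked if s == (votes, qual)],
            )
            provenance = f"consensus:tie-lex({votes} votes)"
        else:
            provenance = f"consensus:{votes} votes"
        out.append((orf_id, "CAZyme", best_fam, provenance))
    result = _assignment_frame(out)
    assert not result["orf_id"].duplicated().any()
    return result


# ---------------------------------------------------------------------------
# Peptidases
# ---------------------------------------------------------------------------

def classify_peptidases(
    profile_hits: pd.DataFrame, merops_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map Pfam peptidase hits to MEROPS families; best scoring hit per ORF.

    Returns (assignments, unmapped side report).  Unmapped accessions are
    never fatal: they are dropped from the assignments and reported.
    """
    if profile_hits.empty:
        return _assignment_frame([]), profile_hits.copy()
    mapping = dict(zip(merops_map["pfam"], merops_map["merops_family"]))
    hits = profile_hits.copy()
    hits["merops_family"] = hits["pfam"].map(mapping)
    unmapped = hits.loc[hits["merops_family"].isna(), ["orf_id", "pfam", "score"]]
    mapped = hits.dropna(subset=["merops_family"])
    rows = []
    for orf_id, grp in mapped.groupby("orf_id", sort=False):
        best = grp.loc[grp["score"].idxmax()]
        rows.append((orf_id, "PEP", best["merops_family"], f"pfam:{best['pfam']}"))
    return _assignment_frame(rows), unmapped.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Transporters
# ---------------------------------------------------------------------------

def classify_transporters(
    hits: pd.DataFrame, overrides: dict[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """TCDB family per ORF (argmax bit score) after profile-level overrides.

    ``overrides`` maps a profile accession to the corrected
    (family, TC number); the default carries the two known-bad Pfam
    mappings (ammonium channel, chloride channel).
    """
    if overrides is None:
        overrides = DEFAULT_TC_OVERRIDES
    if hits.empty:
        return _assignment_frame([])
    corrected = hits.copy()
    for profile, (family, tc) in overrides.items():
        mask = corrected["profile"] == profile
        corrected.loc[mask, "tcdb_family"] = family
        corrected.loc[mask, "tc_number"] = tc
    bad = ~corrected["tc_number"].astype(str).str.match(TC_NUMBER_RE)
    if bad.any():
        raise StratiscopeError(
            f"malformed TC number {corrected.loc[bad, 'tc_number'].iloc[0]!r} "
            f"for ORF {corrected.loc[bad, 'orf_id'].iloc[0]!r}"
        )
    rows = []
    for orf_id, grp in corrected.groupby("orf_id", sort=False):
        best = grp.loc[grp["score"].idxmax()]
        prov = "override" if best["profile"] in overrides else "tcdb"
        rows.append((orf_id, "TP", f"{best['tcdb_family']}|{best['tc_number']}",
                     f"{prov}:{best['profile']}"))
    return _assignment_frame(rows)


def split_tp_family(family: str) -> tuple[str, str]:
    """Split a stored ``family|tc_number`` transporter label."""
    name, _, tc = family.rpartition("|")
    return name, tc


# ---------------------------------------------------------------------------
# Marker genes
# ---------------------------------------------------------------------------

def assign_markers(marker_hits: pd.DataFrame) -> pd.DataFrame:
    """Keep marker hits that pass the profile's gathering score.

    hcd labels originate from an upstream phylogenetic placement and are
    accepted as given (their provenance records that).
    """
    if marker_hits.empty:
        return _assignment_frame([])
    unknown = set(marker_hits["marker"]) - set(MARKERS)
    if unknown:
        raise StratiscopeError(f"unknown marker label(s): {sorted(unknown)}")
    rows = []
    for _, row in marker_hits.iterrows():
        if row["marker"] == "hcd":
            rows.append((row["orf_id"], "marker", "hcd", "placement (external)"))
        elif bool(row["gathering_pass"]):
            rows.append((row["orf_id"], "marker", row["marker"], "gathering-score"))
    return _assignment_frame(rows)


def combine_assignments(*tables: pd.DataFrame) -> pd.DataFrame:
    """Concatenate per-system assignment tables into one long table."""
    tables = [t for t in tables if t is not None and not t.empty]
    if not tables:
        return _assignment_frame([])
    out = pd.concat(tables, ignore_index=True)
    dup = out.duplicated(subset=["orf_id", "system"], keep=False)
    if (dup & (out["system"] == "CAZyme")).any():
        raise StratiscopeError("multiple CAZyme families for one ORF")
    return out
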