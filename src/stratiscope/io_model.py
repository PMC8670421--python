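"""Core data model, TSV readers/writers, and global input filters.

The counting unit of the whole analysis is the ORF (open reading frame
predicted on assembled transcript contigs).  A :class:`CountMatrix` holds the
ORF x sample raw count table together with per-ORF lengths; taxonomy and
sample metadata travel as plain :class:`pandas.DataFrame` tables with a fixed
column contract.

Two global input filters are provided: removal of ORFs overlapping predicted
rRNA genes (the overlap detection itself happens upstream and arrives as a
boolean flag in the taxonomy table) and subsetting to prokaryotes
(Bacteria + Archaea).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved sentinel for missing taxonomy at any rank.
UNCLASSIFIED = "unclassified"

#: Taxonomy ranks carried per ORF, highest to lowest.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

VALID_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota", UNCLASSIFIED})

#: Column contract for the sample metadata table.
METADATA_COLUMNS = (
    "sample_id",
    "depth_m",
    "month",
    "replicate",
    "temperature_C",
    "salinity_PSU",
    "oxygen_ml_per_l",
    "chla_ug_per_l",
    "doc_uM",
    "nh4_uM",
    "no3no2_uM",
    "po4_uM",
    "sio2_uM",
    "totN_uM",
    "totP_uM",
)

#: Environmental covariate columns (candidates for ordination predictors).
ENV_COLUMNS = METADATA_COLUMNS[4:]


class StratiscopeError(ValueError):
    """Raised on contract violations in input data."""


@dataclass
class CountMatrix:
    """ORF x sample matrix of non-negative integer transcript counts.

    Parameters
    ----------
    counts
        DataFrame indexed by ``orf_id`` with one column per sample.
    lengths
        Series of ORF lengths in bp, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise StratiscopeError(f"duplicate orf_id(s): {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise StratiscopeError(f"duplicate sample_id(s): {dups[:5]}")
        if not self.lengths.index.equals(idx):
            raise StratiscopeError("lengths index does not match counts index")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.array_equal(vals, np.floor(vals)):
                    bad = idx[np.where(vals != np.floor(vals))[0][0]]
                    raise StratiscopeError(f"non-integer count at ORF {bad!r}")
                self.counts = self.counts.astype(np.int64)
                vals = self.counts.to_numpy()
            if (vals < 0).any():
                bad = idx[np.where((vals < 0).any(axis=1))[0][0]]
                raise StratiscopeError(f"negative count at ORF {bad!r}")
        lens = self.lengths.to_numpy()
        if lens.size and ((lens < 1).any() or not np.array_equal(lens, np.floor(lens))):
            bad = idx[np.where((lens < 1) | (lens != np.floor(lens)))[0][0]]
            raise StratiscopeError(f"invalid length (must be integer >= 1) at ORF {bad!r}")
        self.lengths = self.lengths.astype(np.int64)

    # -- accessors ----------------------------------------------------------
    @property
    def orf_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_orfs(self, orf_ids) -> "CountMatrix":
        """Return a new matrix restricted to ``orf_ids`` (input order kept)."""
        keep = self.counts.index.isin(set(orf_ids))
        return CountMatrix(self.counts.loc[keep].copy(), self.lengths.loc[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lengths.equals(other.lengths)


# ---------------------------------------------------------------------------
# TSV I/O.  Dialect: tab-separated, UTF-8, "." decimal, no quoting --
# chosen for bit-exact round trips.
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountMatrix:
    """Read a counts TSV: columns ``orf_id``, ``length_bp``, then sample ids.

    Raises
    ------
    StratiscopeError
        On duplicate ORF ids, negative/non-integer counts or missing lengths.
    """
    df = pd.read_csv(path, sep="\t", dtype={"orf_id": str})
    for col in ("orf_id", "length_bp"):
        if col not in df.columns:
            raise StratiscopeError(f"counts table missing required column {col!r}")
    if df["length_bp"].isna().any():
        bad = df.loc[df["length_bp"].isna(), "orf_id"].iloc[0]
        raise StratiscopeError(f"missing length for ORF {bad!r}")
    df = df.set_index("orf_id")
    lengths = df["length_bp"]
    counts = df.drop(columns="length_bp")
    if counts.isna().any().any():
        bad = counts.index[counts.isna().any(axis=1)][0]
        raise StratiscopeError(f"missing count at ORF {bad!r}")
    return CountMatrix(counts, lengths)


def write_count_table(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.index.name = "orf_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV: ``orf_id``, the six ranks, ``is_rrna_overlap``.

    Empty rank cells are normalized to the ``unclassified`` sentinel.  A named
    rank below an unclassified one is a contract violation (LCA lineages are
    always prefixes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("orf_id", *TAXONOMY_RANKS, "is_rrna_overlap")
    for col in required:
        if col not in df.columns:
            raise StratiscopeError(f"taxonomy table missing column {col!r}")
    if df["orf_id"].duplicated().any():
        bad = df.loc[df["orf_id"].duplicated(), "orf_id"].iloc[0]
        raise StratiscopeError(f"duplicate taxonomy record for ORF {bad!r}")
    for rank in TAXONOMY_RANKS:
        df[rank] = df[rank].replace("", UNCLASSIFIED)
    bad_dom = ~df["domain"].isin(VALID_DOMAINS)
    if bad_dom.any():
        raise StratiscopeError(
            f"invalid domain {df.loc[bad_dom, 'domain'].iloc[0]!r} "
            f"(expected one of {sorted(VALID_DOMAINS)})"
        )
    # lineage prefix rule: once unclassified, all lower ranks unclassified
    named = np.column_stack([df[r].to_numpy() != UNCLASSIFIED for r in TAXONOMY_RANKS])
    resumed = (~named[:, :-1] & named[:, 1:]).any(axis=1)
    if resumed.any():
        bad = df.loc[resumed, "orf_id"].iloc[0]
        raise StratiscopeError(f"named rank below an unclassified rank for ORF {bad!r}")
    df["is_rrna_overlap"] = df["is_rrna_overlap"].map(_parse_bool)
    return df.set_index("orf_id", drop=False)


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise StratiscopeError(f"cannot parse boolean value {v!r}")


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (one row per sample; see ``METADATA_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise StratiscopeError(f"metadata table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        bad = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise StratiscopeError(f"duplicate metadata record for sample {bad!r}")
    if (df["depth_m"] <= 0).any():
        raise StratiscopeError("depth_m must be > 0 for every sample")
    if "nh4_below_detection" in df.columns:
        df["nh4_below_detection"] = df["nh4_below_detection"].map(_parse_bool)
    return df.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Global input filters
# ---------------------------------------------------------------------------

def _require_taxonomy(cm: CountMatrix, taxonomy: pd.DataFrame) -> None:
    missing = set(cm.orf_ids) - set(taxonomy["orf_id"])
    if missing:
        raise StratiscopeError(
            f"{len(missing)} ORF(s) lack a taxonomy record, e.g. {sorted(missing)[:3]}"
        )


def filter_rrna_overlaps(
    cm: CountMatrix, taxonomy: pd.DataFrame
) -> tuple[CountMatrix, int]:
    """Drop ORFs flagged as overlapping predicted rRNA genes.

    Returns the filtered matrix and the number of ORFs removed.  Relative
    order of survivors is preserved.
    """
    _require_taxonomy(cm, taxonomy)
    flagged = set(taxonomy.loc[taxonomy["is_rrna_overlap"], "orf_id"])
    keep = [o for o in cm.orf_ids if o not in flagged]
    removed = cm.shape[0] - len(keep)
    if not keep:
        logger.warning("rRNA-overlap filter removed every ORF")
    return cm.subset_orfs(keep), removed


def subset_prokaryotes(cm: CountMatrix, taxonomy: pd.DataFrame) -> CountMatrix:
    """Keep only ORFs whose domain is Bacteria or Archaea."""
    _require_taxonomy(cm, taxonomy)
    prok = set(
        taxonomy.loc[taxonomy["domain"].isin(("Bacteria", "Archaea")), "orf_id"]
    )
    keep = [o for o in cm.orf_ids if o in prok]
    if not keep:
        logger.warning("prokaryote subset is empty")
    return cm.subset_orfs(keep)
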