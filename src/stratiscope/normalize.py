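"""Count transformations: cpm, TPM, abundance filtering, Hellinger, SRS.

All transforms operate per sample (column) on a :class:`CountMatrix` and
return a :class:`TransformedMatrix` tagging which transform produced it.

Scaling with ranked subsampling (SRS) normalizes every library to a common
depth ``c_min`` without discarding rank information: counts are scaled by
``c_min/total``, integer parts are kept, and the remaining counts are given
one each to the ORFs with the largest fractional parts (ties resolved by a
seeded random choice).  Column totals are exactly ``c_min`` and every
normalized count sits within 1 of its scaled value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stratiscope.io_model import CountMatrix, StratiscopeError

TRANSFORM_TAGS = ("cpm", "tpm", "hellinger", "srs")


@dataclass
class TransformedMatrix:
    """ORF x sample matrix of transformed abundances."""

    values: pd.DataFrame
    transform_tag: str

    def __post_init__(self) -> None:
        if self.transform_tag not in TRANSFORM_TAGS:
            raise StratiscopeError(f"unknown transform tag {self.transform_tag!r}")

    @property
    def orf_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# transform: {self.transform_tag}\n")
            out = self.values.copy()
            out.index.name = "orf_id"
            out.to_csv(fh, sep="\t", lineterminator="\n")


def _check_nonzero_columns(cm: CountMatrix) -> np.ndarray:
    if cm.shape[0] == 0:
        raise StratiscopeError("empty count matrix")
    totals = cm.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = cm.counts.columns[np.where(totals == 0)[0][0]]
        raise StratiscopeError(f"sample {bad!r} has no counts")
    return totals


def cpm(cm: CountMatrix) -> TransformedMatrix:
    """Counts per million: count / library size x 1e6."""
    totals = _check_nonzero_columns(cm)
    vals = cm.counts.to_numpy(dtype=float) / totals * 1e6
    return TransformedMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns), "cpm"
    )


def tpm(cm: CountMatrix) -> TransformedMatrix:
    """Transcripts per million: length-normalized (per kb) relative abundance."""
    totals = _check_nonzero_columns(cm)
    lengths_kb = cm.lengths.to_numpy(dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise StratiscopeError("zero ORF length")
    rates = cm.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    vals = rates / rates.sum(axis=0) * 1e6
    return TransformedMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns), "tpm"
    )


def hellinger(cm: CountMatrix) -> TransformedMatrix:
    """Square root of per-sample relative abundance (unit-norm columns)."""
    totals = _check_nonzero_columns(cm)
    vals = np.sqrt(cm.counts.to_numpy(dtype=float) / totals)
    return TransformedMatrix(
        pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns),
        "hellinger",
    )


def abundance_filter(
    cm: CountMatrix,
    min_cpm: float = 5.0,
    min_samples: int = 2,
    strict: bool = False,
) -> CountMatrix:
    """Keep ORFs with at least ``min_cpm`` in ``min_samples`` or more samples.

    The comparison is ``>=`` by default (``strict=True`` switches to ``>``);
    raw counts, not cpm values, are returned for the survivors.  The filter
    is applied once to the matrix it is given -- re-filtering the survivor
    matrix can remove further ORFs because cpm denominators shrink.
    """
    c = cpm(cm).values.to_numpy()
    passing = (c > min_cpm) if strict else (c >= min_cpm)
    keep = passing.sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep].copy(), cm.lengths.loc[keep].copy())


def srs_normalize(
    cm: CountMatrix, c_min: int | str = "auto", seed: int = 0
) -> TransformedMatrix:
    """Scale every library to ``c_min`` counts by ranked subsampling.

    ``c_min="auto"`` uses the smallest library.  Upsampling is refused:
    ``c_min`` may not exceed any column total.
    """
    totals = _check_nonzero_columns(cm)
    if c_min == "auto":
        c_min = int(totals.min())
    c_min = int(c_min)
    if c_min < 1:
        raise StratiscopeError("c_min must be >= 1")
    too_small = totals < c_min
    if too_small.any():
        bad = cm.counts.columns[np.where(too_small)[0][0]]
        raise StratiscopeError(
            f"c_min={c_min} exceeds the library size of sample {bad!r} (no upsampling)"
        )
    rng = np.random.default_rng(seed)
    counts = cm.counts.to_numpy(dtype=float)
    out = np.zeros_like(counts, dtype=np.int64)
    n = counts.shape[0]
    for j, total in enumerate(totals):
        scaled = counts[:, j] * (c_min / total)
        base = np.floor(scaled).astype(np.int64)
        frac = scaled - base
        delta = c_min - int(base.sum())
        if delta:
            # rank by fractional part, ties shuffled by the seeded RNG
            tiebreak = rng.permutation(n)
            order = np.lexsort((tiebreak, -frac))
            base[order[:delta]] += 1
        out[:, j] = base
    return TransformedMatrix(
        pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns), "srs"
    )
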