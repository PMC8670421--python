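"""Independent brute-force oracles used to check the implementations."""

import itertools

import numpy as np
import pandas as pd


def brute_force_consensus(records, hits_cap=100):
    """Reference CAZyme consensus, written as plain enumeration.

    ``records`` is a list of dicts with keys orf_id, tool, family and the
    tool's metrics.  Returns {orf_id: family or None}.
    """
    by_orf = {}
    for r in records:
        by_orf.setdefault(r["orf_id"], []).append(r)
    out = {}
    for orf, recs in by_orf.items():
        if len(recs) == 1:
            r = recs[0]
            ok = (
                (r["tool"] == "alignment" and r["percent_identity"] >= 50.0)
                or (r["tool"] == "profile" and r["coverage"] >= 0.5)
                or (r["tool"] == "pattern" and r["hits"] >= 10)
            )
            out[orf] = r["family"] if ok else None
            continue
        max_freq = max(
            [r["frequency"] for r in recs if r["tool"] == "pattern"], default=0.0
        )
        families = sorted({r["family"] for r in recs})
        best, best_key = None, None
        for fam in families:
            votes, quality = 0, 0.0
            for r in recs:
                if r["family"] != fam:
                    continue
                votes += 1
                if r["tool"] == "alignment":
                    quality += r["percent_identity"] / 100.0
                elif r["tool"] == "profile":
                    quality += r["coverage"]
                else:
                    rel = r["frequency"] / max_freq if max_freq > 0 else 1.0
                    quality += min(1.0, r["hits"] / hits_cap) * rel
            key = (votes, quality)
            if best_key is None or key > best_key:
                best, best_key = fam, key
            # ties: families iterated in lexicographic order, first kept
        out[orf] = best
    return out


def consensus_boundary_grid():
    """Exhaustive tool-combination x boundary-metric fixture grid.

    Every nonempty subset of tools crossed with below/at/above-threshold
    metric levels for each tool present (>= 3^1 + 3^2 + 3^3 cases per
    family layout).
    """
    levels = {
        "alignment": [("below", 49.9), ("at", 50.0), ("above", 80.0)],
        "profile": [("below", 0.49), ("at", 0.5), ("above", 0.9)],
        "pattern": [("below", 9), ("at", 10), ("above", 40)],
    }
    records = []
    case_id = 0
    for tool_subset in (
        ("alignment",), ("profile",), ("pattern",),
        ("alignment", "profile"), ("alignment", "pattern"),
        ("profile", "pattern"), ("alignment", "profile", "pattern"),
    ):
        for combo in itertools.product(*(levels[t] for t in tool_subset)):
            for fam_layout in ("agree", "split"):
                orf = f"case{case_id:04d}"
                case_id += 1
                for k, (tool, (_, val)) in enumerate(zip(tool_subset, combo)):
                    fam = "GH16" if (fam_layout == "agree" or k == 0) else "GH13"
                    rec = dict(
                        orf_id=orf, tool=tool, family=fam,
                        percent_identity=np.nan, coverage=np.nan,
                        hits=np.nan, frequency=np.nan,
                    )
                    if tool == "alignment":
                        rec["percent_identity"] = val
                    elif tool == "profile":
                        rec["coverage"] = val
                    else:
                        rec["hits"] = val
                        rec["frequency"] = 0.5
                    records.append(rec)
    return pd.DataFrame(records)
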