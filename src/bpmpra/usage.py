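"""Acceptor-usage summaries, SA1 minigene partition and novel-3'SS context.

Usage is quantified both at the transcript level (reads to each acceptor
class over total reads) and at the minigene level (fraction of minigenes
with at least one SA1 read).  SA1-utilizing minigenes are partitioned into
shared / mutant-only / wild-type-only sets across the two conditions, and
the sequence context upstream of novel acceptors (those inside the
degenerate regions; SA1 and SA2 are excluded because their immediate
upstream context is invariant) is summarised as a position frequency
matrix suitable for logo tools.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import Minigene

__all__ = [
    "usage_fractions",
    "sa1_fold_change",
    "partition_sa1",
    "novel_ss_context",
    "write_pfm",
]

CLASSES = ("SA1", "SA2", "NOVEL")


def _sa1_minigenes(table: pd.DataFrame) -> set:
    return set(table.loc[table["acceptor_class"] == "SA1", "minigene_id"])


def usage_fractions(table: pd.DataFrame) -> dict:
    """Transcript-level class fractions and minigene-level SA1 usage ratio.

    An empty table yields ``{"empty": True}`` with undefined fractions.
    """
    total = int(table["n_reads"].sum()) if len(table) else 0
    if total == 0:
        return {"empty": True, "n_reads": 0, "transcript_fractions": None,
                "minigene_sa1_ratio": None}
    by_class = table.groupby("acceptor_class")["n_reads"].sum()
    fractions = {cls: float(by_class.get(cls, 0)) / total for cls in CLASSES}
    n_minigenes = table["minigene_id"].nunique()
    return {
        "empty": False,
        "n_reads": total,
        "n_minigenes": int(n_minigenes),
        "transcript_fractions": fractions,
        "minigene_sa1_ratio": len(_sa1_minigenes(table)) / n_minigenes,
    }


def sa1_fold_change(summary_wt: dict, summary_k700e: dict) -> float:
    """K700E/WT ratio of transcript-level SA1 fractions."""
    fw = summary_wt["transcript_fractions"]["SA1"]
    fk = summary_k700e["transcript_fractions"]["SA1"]
    if fw == 0:
        return float("inf") if fk > 0 else float("nan")
    return fk / fw


def partition_sa1(table_wt: pd.DataFrame, table_k700e: pd.DataFrame) -> dict:
    """Partition SA1-utilizing minigenes into shared / K700E-only / WT-only.

    A minigene "utilizes SA1" in a condition iff it has >= 1 SA1 transcript
    record there; the three sets are disjoint and cover the SA1 universe.
    """
    wt, k7 = _sa1_minigenes(table_wt), _sa1_minigenes(table_k700e)
    universe = wt | k7
    n = len(universe)
    counts = {
        "shared": len(wt & k7),
        "k700e_only": len(k7 - wt),
        "wt_only": len(wt - k7),
    }
    pct = {key: (100.0 * v / n if n else 0.0) for key, v in counts.items()}
    return {"n_sa1_minigenes": n, "counts": counts, "percent": pct}


def novel_ss_context(
    table: pd.DataFrame,
    library: Sequence[Minigene] | Mapping[str, Minigene],
    width: int = 20,
) -> tuple[list[str], pd.DataFrame]:
    """Upstream windows of novel acceptors and their position frequency matrix.

    One ``width``-nt window ending at each distinct novel acceptor site
    (minigene x position); windows escaping the minigene are skipped.  The
    PFM has rows A, C, G, T and columns summing to the number of windows.
    """
    by_id = library if isinstance(library, Mapping) else {m.id: m for m in library}
    novel = table[table["acceptor_class"] == "NOVEL"]
    sites = novel[["minigene_id", "acceptor_pos"]].drop_duplicates()
    seqs: list[str] = []
    n_skipped = 0
    for row in sites.itertuples(index=False):
        pos = int(row.acceptor_pos)
        if pos < width:
            n_skipped += 1
            continue
        seqs.append(by_id[row.minigene_id].full_seq[pos - width : pos])
    pfm = np.zeros((4, width), dtype=int)
    rows = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in seqs:
        for j, ch in enumerate(s):
            pfm[rows[ch], j] += 1
    df = pd.DataFrame(pfm, index=list("ACGT"), columns=range(-width, 0))
    df.attrs["n_sequences"] = len(seqs)
    df.attrs["n_skipped"] = n_skipped
    return seqs, df


def write_pfm(pfm: pd.DataFrame, path) -> None:
    """Write a PFM as a plain-text matrix (rows A, C, G, T)."""
    pfm.to_csv(path, sep="\t", index_label="base")
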