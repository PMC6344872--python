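"""Per-6-mer odds-ratio statistics for SA1 usage and branch-point motif census.

For each of the 4096 6-mers, a 2x2 table is built over the filtered minigene
universe of one condition: does the minigene use SA1 (>= 1 SA1 read) x does
its degenerate region (25A or 25B) contain the 6-mer.  The odds ratio

    OR = ((a + p) * (d + p)) / ((b + p) * (c + p))

(Haldane-Anscombe pseudocount p, default 0.5) measures how strongly the
6-mer enhances (OR > 1) or represses (OR < 1) SA1 selection.  The condition
contrast Delta_log2 = log2 OR(K700E) - log2 OR(WT) ranks 6-mers that enhance
splicing more in the mutant.

6-mers are classified against the canonical branch-point core TAA (positions
-2, -1, 0 with 0 the branch adenosine) by a total, hierarchical rule:
contains TAA -> CANONICAL_TAA; else T[CGT]A -> MINUS1_VARIANT; else
[ACG]AA -> MINUS2_VARIANT; else any trinucleotide ending in A with neither a
-2 T nor a -1 A -> BOTH_VARIANT; else NONE.  Under this hierarchy ~16% of
all 4096 6-mers are -1 variants, the background against which mutant-specific
enhancers are compared.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import Minigene

__all__ = [
    "MotifClass",
    "ALL_6MERS",
    "kmer_presence",
    "odds_ratio",
    "compute_all",
    "delta_log2",
    "classify_kmer",
    "classification_census",
    "top_enhancers",
]

REGIONS = ("25A", "25B")


class MotifClass(enum.Enum):
    CANONICAL_TAA = "CANONICAL_TAA"
    MINUS1_VARIANT = "MINUS1_VARIANT"
    MINUS2_VARIANT = "MINUS2_VARIANT"
    BOTH_VARIANT = "BOTH_VARIANT"
    NONE = "NONE"


ALL_6MERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_KMER_INDEX = {k: i for i, k in enumerate(ALL_6MERS)}
_VALID = set("ACGT")


def kmer_presence(seq: str, k: int = 6) -> set[str]:
    """Set of distinct k-mers present in ``seq`` (empty if ``len(seq) < k``)."""
    if len(seq) < k:
        warnings.warn(f"sequence shorter than k={k}; empty k-mer set", stacklevel=2)
        return set()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def odds_ratio(a: int, b: int, c: int, d: int, pseudocount: float = 0.5) -> float:
    """Odds ratio of a 2x2 presence table with a Haldane-Anscombe pseudocount."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both margins of the 2x2 table must be positive")
    p = pseudocount
    num = (a + p) * (d + p)
    den = (b + p) * (c + p)
    if den == 0:
        return math.inf
    return num / den


def _region_seq(mg: Minigene, region: str) -> str:
    if region == "25A":
        return mg.n25a
    if region == "25B":
        return mg.n25b
    raise ValueError(f"region must be one of {REGIONS}")


def compute_all(
    library: Sequence[Minigene] | Mapping[str, Minigene],
    table: pd.DataFrame,
    region: str,
    pseudocount: float = 0.5,
    k: int = 6,
) -> pd.DataFrame:
    """Cross-tabulate SA1 usage against 6-mer presence in one degenerate region.

    ``table`` is a filtered single-condition transcript table (columns
    minigene_id, condition, acceptor_class, n_reads).  The universe is every
    minigene in ``table``; the SA1 set is those with >= 1 SA1 read.  Returns
    one row per 6-mer with cells a/b/c/d, the odds ratio and log2 OR.
    """
    by_id = library if isinstance(library, Mapping) else {m.id: m for m in library}
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    universe = pd.unique(table["minigene_id"])
    sa1_ids = set(table.loc[table["acceptor_class"] == "SA1", "minigene_id"])
    if not sa1_ids:
        cond = table["condition"].iloc[0] if len(table) else "?"
        raise ValueError(f"no SA1-utilizing minigenes in condition {cond}")
    n_sa1 = len(sa1_ids)
    n_non = len(universe) - n_sa1
    contain_all = np.zeros(len(ALL_6MERS), dtype=np.int64)
    contain_sa1 = np.zeros(len(ALL_6MERS), dtype=np.int64)
    for mg_id in universe:
        seq = _region_seq(by_id[mg_id], region)
        idxs = [_KMER_INDEX[km] for km in kmer_presence(seq, k)]
        contain_all[idxs] += 1
        if mg_id in sa1_ids:
            contain_sa1[idxs] += 1
    a = contain_sa1
    b = n_sa1 - a
    c = contain_all - contain_sa1
    d = n_non - c
    p = pseudocount
    with np.errstate(divide="ignore"):
        orr = (a + p) * (d + p) / ((b + p) * (c + p))
    df = pd.DataFrame(
        {
            "kmer": ALL_6MERS,
            "region": region,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "odds_ratio": orr,
            "log2_or": np.log2(orr),
        }
    )
    return df


def delta_log2(stats_wt: pd.DataFrame, stats_k700e: pd.DataFrame) -> pd.DataFrame:
    """Per-6-mer condition contrast Delta_log2 = log2 OR(K700E) - log2 OR(WT)."""
    if list(stats_wt["kmer"]) != list(stats_k700e["kmer"]):
        raise ValueError("k-mer universes of the two condition tables differ")
    regions = set(stats_wt["region"]) | set(stats_k700e["region"])
    if len(regions) != 1:
        raise ValueError("condition tables must cover the same single region")
    out = pd.DataFrame(
        {
            "kmer": stats_wt["kmer"].to_numpy(),
            "region": stats_wt["region"].to_numpy(),
            "or_wt": stats_wt["odds_ratio"].to_numpy(),
            "or_k700e": stats_k700e["odds_ratio"].to_numpy(),
            "log2_or_wt": stats_wt["log2_or"].to_numpy(),
            "log2_or_k700e": stats_k700e["log2_or"].to_numpy(),
        }
    )
    out["delta_log2"] = out["log2_or_k700e"] - out["log2_or_wt"]
    return out


def classify_kmer(kmer: str) -> MotifClass:
    """Hierarchical branch-point classification of a 6-mer (first match wins)."""
    if not set(kmer) <= _VALID:
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    tris = [kmer[i : i + 3] for i in range(len(kmer) - 2)]
    if any(t == "TAA" for t in tris):
        return MotifClass.CANONICAL_TAA
    if any(t[0] == "T" and t[1] in "CGT" and t[2] == "A" for t in tris):
        return MotifClass.MINUS1_VARIANT
    if any(t[0] in "ACG" and t[1] == "A" and t[2] == "A" for t in tris):
        return MotifClass.MINUS2_VARIANT
    if any(t[2] == "A" and t[0] != "T" and t[1] != "A" for t in tris):
        return MotifClass.BOTH_VARIANT
    return MotifClass.NONE


def classification_census() -> pd.DataFrame:
    """Counts and percentages of every motif class over all 4096 6-mers."""
    counts = {cls: 0 for cls in MotifClass}
    for km in ALL_6MERS:
        counts[classify_kmer(km)] += 1
    total = len(ALL_6MERS)
    return pd.DataFrame(
        {
            "motif_class": [cls.value for cls in MotifClass],
            "count": [counts[cls] for cls in MotifClass],
            "percent": [100.0 * counts[cls] / total for cls in MotifClass],
        }
    )


def top_enhancers(
    stats: pd.DataFrame, or_threshold: float = 1.5, by: str = "delta"
) -> tuple[pd.DataFrame, dict]:
    """Rank splicing-enhancing 6-mers and annotate branch-point classes.

    ``stats`` is a :func:`delta_log2` table.  Survivors must exceed
    ``or_threshold`` in the K700E condition; for ``by="delta"`` (mutant-
    preferred enhancers) they must additionally enhance more in K700E
    (Delta_log2 > 0) and are ranked by Delta_log2, while ``by="OR"`` ranks
    by the K700E odds ratio.  Returns the ranked table plus the motif-class
    share (percent) among survivors.
    """
    if by not in ("delta", "OR"):
        raise ValueError("by must be 'delta' or 'OR'")
    surv = stats[stats["or_k700e"] > or_threshold].copy()
    if by == "delta":
        surv = surv[surv["delta_log2"] > 0]
        surv = surv.sort_values("delta_log2", ascending=False, kind="mergesort")
    else:
        surv = surv.sort_values("or_k700e", ascending=False, kind="mergesort")
    surv["motif_class"] = [classify_kmer(km).value for km in surv["kmer"]]
    if len(surv) == 0:
        warnings.warn("no 6-mer survives the OR threshold", stacklevel=2)
        shares = {cls.value: 0.0 for cls in MotifClass}
    else:
        vc = surv["motif_class"].value_counts()
        shares = {cls.value: 100.0 * vc.get(cls.value, 0) / len(surv) for cls in MotifClass}
    return surv.reset_index(drop=True), shares
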