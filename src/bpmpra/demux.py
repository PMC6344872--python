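"""Barcode demultiplexing, splice-junction calling and representation filters.

Read pairs are assigned to minigenes by the 20-bp barcode carried at the
start of read 2 (exact match first, then a unique Hamming neighbour within
``max_mismatch``; ties are left unassigned).  Read 1 is then matched against
minigene-local isoform references -- exon 1 joined to each candidate
acceptor's downstream sequence -- allowing at most one substitution; a call
requires a unique best isoform whose junction is covered by at least
``min_flank`` nt on each side.

The representation filter keeps a minigene only when its summed reads reach
``min_reads`` (default 5) in every required condition, mirroring the
assay's "present in both datasets at a minimum of five reads" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import Minigene, novel_acceptor_positions

__all__ = [
    "FilterConfig",
    "build_barcode_index",
    "match_barcode",
    "isoform_references",
    "call_junction",
    "build_transcript_table",
    "apply_filters",
    "truth_to_table",
]

TABLE_COLUMNS = ["minigene_id", "condition", "acceptor_class", "acceptor_pos", "n_reads"]


@dataclass(frozen=True)
class FilterConfig:
    min_reads: int = 5
    require_both_conditions: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def build_barcode_index(library: Sequence[Minigene]) -> dict[str, str]:
    """Map barcode -> minigene id; duplicate barcodes fail loudly."""
    index: dict[str, str] = {}
    for mg in library:
        if mg.barcode in index:
            raise ValueError(f"duplicate barcode {mg.barcode} ({index[mg.barcode]}, {mg.id})")
        index[mg.barcode] = mg.id
    return index


def _neighbors1(seq: str):
    for i, ch in enumerate(seq):
        for b in "ACGT":
            if b != ch:
                yield seq[:i] + b + seq[i + 1 :]


def match_barcode(
    r2_seq: str, barcode_index: Mapping[str, str], max_mismatch: int = 1
) -> str | None:
    """Assign a read-2 sequence to a minigene id, or ``None`` if unassigned.

    An exact barcode prefix match wins outright; otherwise the unique index
    entry at minimal Hamming distance <= ``max_mismatch`` wins, and ties or
    absent matches are unassigned.
    """
    if not barcode_index:
        raise ValueError("empty barcode index")
    blen = len(next(iter(barcode_index)))
    if len(r2_seq) < blen:
        return None
    prefix = r2_seq[:blen]
    hit = barcode_index.get(prefix)
    if hit is not None:
        return hit
    if max_mismatch <= 0:
        return None
    if max_mismatch == 1:
        hits = {barcode_index[v] for v in _neighbors1(prefix) if v in barcode_index}
        return hits.pop() if len(hits) == 1 else None
    # general (slow) path: full scan at arbitrary mismatch budget
    best_d, best_ids = max_mismatch + 1, set()
    for bc, mg_id in barcode_index.items():
        d = sum(a != b for a, b in zip(prefix, bc))
        if d < best_d:
            best_d, best_ids = d, {mg_id}
        elif d == best_d:
            best_ids.add(mg_id)
    return best_ids.pop() if best_d <= max_mismatch and len(best_ids) == 1 else None


def isoform_references(mg: Minigene) -> list[tuple[str, int, str]]:
    """(acceptor label, acceptor position, spliced reference) per candidate."""
    refs = [("SA1", mg.sa1_pos), ("SA2", mg.sa2_pos)]
    refs.extend(("NOVEL", p) for p in novel_acceptor_positions(mg))
    exon1 = mg.full_seq[: mg.donor_pos]
    return [(label, pos, exon1 + mg.full_seq[pos:]) for label, pos in refs]


def _junction_hits_exact(read: str, ref: str, junction: int, min_flank: int) -> bool:
    start = ref.find(read)
    while start != -1:
        if start <= junction - min_flank and start + len(read) >= junction + min_flank:
            return True
        start = ref.find(read, start + 1)
    return False


def _best_hamming(read: str, ref: str, junction: int, min_flank: int, max_sub: int) -> int | None:
    """Minimal substitution count of any junction-covering alignment, if <= max_sub."""
    if len(ref) < len(read):
        return None
    lo = max(0, junction + min_flank - len(read))
    hi = junction - min_flank
    if hi < lo:
        return None
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(ref_arr, len(read))[lo : hi + 1]
    if win.size == 0:
        return None
    mism = (win != read_arr).sum(axis=1)
    best = int(mism.min())
    return best if best <= max_sub else None


def call_junction(
    r1_seq: str,
    minigene: Minigene,
    min_flank: int = 15,
    refs: Sequence[tuple[str, int, str]] | None = None,
) -> tuple[str, int] | None:
    """Call the acceptor used by read 1 against one minigene's isoform set.

    Returns (acceptor label, acceptor position) or ``None`` (uncalled) when
    no isoform matches within one substitution with the junction covered by
    ``min_flank`` nt on each side, or when the best isoform is not unique.
    """
    if refs is None:
        refs = isoform_references(minigene)
    junction = minigene.donor_pos
    exact = [
        (label, pos)
        for label, pos, ref in refs
        if _junction_hits_exact(r1_seq, ref, junction, min_flank)
    ]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        return None
    scored = []
    for label, pos, ref in refs:
        best = _best_hamming(r1_seq, ref, junction, min_flank, max_sub=1)
        if best is not None:
            scored.append((best, label, pos))
    if not scored:
        return None
    scored.sort(key=lambda t: t[0])
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return None
    return scored[0][1], scored[0][2]


def build_transcript_table(
    r1_path: str | Path,
    r2_path: str | Path,
    library: Sequence[Minigene],
    condition: str,
    max_mismatch: int = 1,
    min_flank: int = 15,
) -> tuple[pd.DataFrame, dict]:
    """Demultiplex a FASTQ pair into aggregated transcript records.

    Returns (table, report); the report tallies assigned / unassigned /
    uncalled pairs, which sum to the number of input pairs.
    """
    by_id = {mg.id: mg for mg in library}
    index = build_barcode_index(library)
    refs_cache: dict[str, list] = {}
    counts: dict[tuple[str, str, int], int] = {}
    n_pairs = n_unassigned = n_uncalled = 0
    with open(r1_path) as f1, open(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for rec1, rec2 in zip_longest(it1, it2):
            if rec1 is None or rec2 is None:
                raise ValueError(f"FASTQ pair out of sync after record {n_pairs}")
            n_pairs += 1
            mg_id = match_barcode(rec2[1], index, max_mismatch)
            if mg_id is None:
                n_unassigned += 1
                continue
            mg = by_id[mg_id]
            refs = refs_cache.get(mg_id)
            if refs is None:
                refs = refs_cache[mg_id] = isoform_references(mg)
            call = call_junction(rec1[1], mg, min_flank, refs)
            if call is None:
                n_uncalled += 1
                continue
            key = (mg_id, call[0], call[1])
            counts[key] = counts.get(key, 0) + 1
    rows = [
        (mg_id, condition, label, pos, n)
        for (mg_id, label, pos), n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    report = {
        "condition": condition,
        "n_pairs": n_pairs,
        "assigned": n_pairs - n_unassigned - n_uncalled,
        "unassigned": n_unassigned,
        "uncalled": n_uncalled,
    }
    return table, report


def apply_filters(
    tables: Mapping[str, pd.DataFrame], cfg: FilterConfig = FilterConfig()
) -> dict[str, pd.DataFrame]:
    """Keep minigenes meeting ``min_reads`` in every required condition.

    With ``require_both_conditions`` the kept set is the intersection over
    all supplied condition tables; otherwise each table is filtered on its
    own counts.  Idempotent.
    """
    if cfg.require_both_conditions and len(tables) < 2:
        raise ValueError("require_both_conditions needs at least two condition tables")
    sums = {
        cond: t.groupby("minigene_id")["n_reads"].sum() for cond, t in tables.items()
    }
    if cfg.require_both_conditions:
        kept: set | None = None
        for s in sums.values():
            ids = set(s[s >= cfg.min_reads].index)
            kept = ids if kept is None else kept & ids
        return {
            cond: t[t["minigene_id"].isin(kept)].reset_index(drop=True)
            for cond, t in tables.items()
        }
    return {
        cond: t[t["minigene_id"].isin(set(s[s >= cfg.min_reads].index))].reset_index(drop=True)
        for (cond, t), s in zip(tables.items(), sums.values())
    }


def truth_to_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Convert a simulator truth table into the transcript-record schema."""
    out = truth.rename(columns={"count": "n_reads"})[TABLE_COLUMNS].copy()
    return out
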