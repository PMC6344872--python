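"""Synthetic two-acceptor minigene libraries and condition-dependent splicing.

The reporter construct mirrors a massively parallel 3' splice-site competition
assay: a single-intron minigene with two competing splice acceptors, SA1 and
SA2, 156 bp apart.  SA1 is flanked by two 25-nt fully degenerate regions
(N25A immediately upstream, N25B downstream within the inter-acceptor
segment) whose random content determines how strongly SA1 competes; SA2 sits
behind an invariant strong branch point (CTAAC, branch adenosine 29 bp
upstream) and polypyrimidine tract and is the predominant acceptor.  A unique
20-bp barcode downstream of exon 2 identifies each minigene in read 2 of a
paired-end sequencing readout.

Acceptor choice is modelled as a softmax over per-acceptor log-weights::

    log w(a) = beta_bp * (-dG_bp(a, mode)) + beta_ppt * pyr20(a) + baseline(a)

where ``dG_bp`` is the best U2-BP duplex energy in a search window upstream
of the acceptor (:mod:`bpmpra.energy`), ``pyr20`` the pyrimidine fraction of
the 20 nt immediately upstream, and the baseline is ``sa2_bonus`` for SA2,
0 for SA1 and ``novel_penalty`` for novel acceptors (AG dinucleotides inside
the degenerate regions).  The mutant condition (K700E) differs from the wild
type only through ``lambda_minus1``: mutant spliceosomes discount the -1
branch-point mismatch penalty, stabilising non-canonical branch points whose
base 5' of the branch adenosine deviates from A.  lambda = 1 makes the two
conditions identical.

Coordinates are 0-based half-open throughout; an acceptor position is the
first exonic base.  The construct is single-stranded (plus strand only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import DuplexParams, predict_bp

__all__ = [
    "ScaffoldConfig",
    "Minigene",
    "SpliceModelParams",
    "DEFAULT_SCAFFOLD",
    "generate_library",
    "base_minigene",
    "make_minigene",
    "novel_acceptor_positions",
    "acceptor_weights",
    "simulate_transcripts",
    "emit_reads",
    "write_library_tsv",
    "read_library_tsv",
]

WT = "WT"
K700E = "K700E"
CONDITIONS = (WT, K700E)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_VALID = set("ACGT")

# Invariant scaffold segments.  The intron's final 18 nt and the SA2-proximal
# filler are adenosine-free so that, within the BP search window, SA1's branch
# point candidates come only from the degenerate N25A and SA2's only from the
# planted canonical ACTAAC (branch A 29 bp upstream of SA2).
_EXON1 = "ATGGTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTGGTCGAGCTGGAC"
_INTRON_5P = "GTAAGTATCCAGGCTCGCGGTTGGCGTCGCTGCTTCGGTCTCC"
_SA1_GAP = "TTTCCAG"  # invariant pyrimidine-rich heptamer ending in the SA1 AG
_INTER_TEMPLATE = (
    "GGCGACGGCA"
    + "N" * 25  # N25B slot, 10 nt downstream of SA1
    + "TGGACGGCAACTACAAGACCCGCGCCGAGGTGAAGTTCGAGGGCGACACCCTGGTGAACCGCATCGAGCTG"
    + "GGTTGGCTGTCGGTTGG"
    + "ACTAAC"  # SA2 branch point; branch adenosine at SA2 - 29
    + "GTGGCTGTCGCTG"
    + "TCCTTTCCTTTC"  # SA2 polypyrimidine tract
    + "AG"
)
_EXON2 = "GACGAGCTGTACAAGTCCGGACTCAGATCTCGAGCTCAAG"
_TAIL = "CTCGACTGTGCCTTCTAGTTGCCAGCCATCTGTTGTTTGC"


@dataclass(frozen=True)
class ScaffoldConfig:
    """Invariant geometry and sequence of the minigene scaffold."""

    exon1_seq: str = _EXON1
    intron_5p_seq: str = _INTRON_5P
    sa1_gap_seq: str = _SA1_GAP
    inter_acceptor_seq: str = _INTER_TEMPLATE  # 156 nt, 25 Ns mark the N25B slot
    exon2_seq: str = _EXON2
    tail_seq: str = _TAIL
    n25a_offset: int = 7  # end of N25A relative to SA1
    sa1_sa2_distance: int = 156
    barcode_len: int = 20
    degenerate_len: int = 25

    def __post_init__(self) -> None:
        for name in ("exon1_seq", "intron_5p_seq", "sa1_gap_seq", "exon2_seq", "tail_seq"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= _VALID:
                raise ValueError(f"{name} must be nonempty over ACGT")
        if len(self.inter_acceptor_seq) != self.sa1_sa2_distance:
            raise ValueError("inter_acceptor_seq length must equal sa1_sa2_distance")
        if self.inter_acceptor_seq.count("N") != self.degenerate_len:
            raise ValueError("inter_acceptor_seq must contain one N25B slot of Ns")
        if "N" * self.degenerate_len not in self.inter_acceptor_seq:
            raise ValueError("N25B slot must be contiguous")
        if len(self.sa1_gap_seq) != self.n25a_offset:
            raise ValueError("sa1_gap_seq length must equal n25a_offset")
        if not self.sa1_gap_seq.endswith("AG"):
            raise ValueError("SA1 acceptor context must end in AG")

    # -- derived coordinates (0-based, on the assembled minigene) ---------
    @property
    def donor_pos(self) -> int:
        return len(self.exon1_seq)

    @property
    def n25a_start(self) -> int:
        return len(self.exon1_seq) + len(self.intron_5p_seq)

    @property
    def sa1_pos(self) -> int:
        return self.n25a_start + self.degenerate_len + self.n25a_offset

    @property
    def sa2_pos(self) -> int:
        return self.sa1_pos + self.sa1_sa2_distance

    @property
    def n25b_start(self) -> int:
        return self.sa1_pos + self.inter_acceptor_seq.index("N")

    @property
    def barcode_start(self) -> int:
        return self.sa2_pos + len(self.exon2_seq)

    def assemble(self, barcode: str, n25a: str, n25b: str) -> str:
        inter = self.inter_acceptor_seq.replace("N" * self.degenerate_len, n25b)
        return (
            self.exon1_seq
            + self.intron_5p_seq
            + n25a
            + self.sa1_gap_seq
            + inter
            + self.exon2_seq
            + barcode
            + self.tail_seq
        )


DEFAULT_SCAFFOLD = ScaffoldConfig()


@dataclass(frozen=True)
class Minigene:
    """One assembled library member."""

    id: str
    barcode: str
    n25a: str
    n25b: str
    full_seq: str
    sa1_pos: int
    sa2_pos: int
    donor_pos: int
    n25a_start: int
    n25b_start: int
    barcode_start: int

    def __post_init__(self) -> None:
        if self.sa2_pos - self.sa1_pos != 156:
            raise ValueError("SA1-SA2 spacing must be 156 bp")
        if self.full_seq[self.n25a_start : self.n25a_start + len(self.n25a)] != self.n25a:
            raise ValueError("n25a not at its configured offset")
        if self.full_seq[self.n25b_start : self.n25b_start + len(self.n25b)] != self.n25b:
            raise ValueError("n25b not at its configured offset")


def make_minigene(mg_id: str, barcode: str, n25a: str, n25b: str, scaffold: ScaffoldConfig) -> Minigene:
    return Minigene(
        id=mg_id,
        barcode=barcode,
        n25a=n25a,
        n25b=n25b,
        full_seq=scaffold.assemble(barcode, n25a, n25b),
        sa1_pos=scaffold.sa1_pos,
        sa2_pos=scaffold.sa2_pos,
        donor_pos=scaffold.donor_pos,
        n25a_start=scaffold.n25a_start,
        n25b_start=scaffold.n25b_start,
        barcode_start=scaffold.barcode_start,
    )


@dataclass
class SpliceModelParams:
    """Weights of the acceptor-competition model."""

    beta_bp: float = 1.0
    beta_ppt: float = 2.0
    # residual SA2 baseline beyond its strong invariant BP/PPT context;
    # calibrated so that with the default scaffold ~37% of minigenes use SA1
    # at least once at depth ~50 while SA2 stays the predominant acceptor
    sa2_bonus: float = -1.3
    novel_penalty: float = -4.0
    lambda_minus1: float = 1.0
    bp_search_window: tuple[int, int] = (-50, -10)
    seed: int = 0
    duplex: DuplexParams = field(default_factory=DuplexParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_minus1 <= 1.0:
            raise ValueError("lambda_minus1 must lie in [0, 1]")
        for name in ("beta_bp", "beta_ppt", "sa2_bonus", "novel_penalty"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        # the duplex model carries the same lambda so that both the
        # generative weights and descriptive energy calls agree
        object.__setattr__(self, "duplex", replace(self.duplex, lambda_minus1=self.lambda_minus1))


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return [b"".join(_BASES[row]).decode() for row in draws]


def generate_library(
    n_minigenes: int,
    scaffold: ScaffoldConfig = DEFAULT_SCAFFOLD,
    seed: int = 0,
) -> list[Minigene]:
    """Generate ``n_minigenes`` members with unique barcodes and i.i.d. uniform
    degenerate inserts, deterministically under ``seed``."""
    if n_minigenes < 1:
        raise ValueError("n_minigenes must be >= 1")
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(barcodes) < n_minigenes:
        need = n_minigenes - len(barcodes)
        for bc in _random_seqs(rng, need, scaffold.barcode_len):
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
        attempts += 1
        if attempts > 100:
            raise RuntimeError("barcode space exhausted; increase barcode_len")
    n25a = _random_seqs(rng, n_minigenes, scaffold.degenerate_len)
    n25b = _random_seqs(rng, n_minigenes, scaffold.degenerate_len)
    width = max(6, len(str(n_minigenes)))
    return [
        make_minigene(f"MG{i:0{width}d}", barcodes[i], n25a[i], n25b[i], scaffold)
        for i in range(n_minigenes)
    ]


def base_minigene(scaffold: ScaffoldConfig = DEFAULT_SCAFFOLD) -> Minigene:
    """The invariant base construct: a canonical CTAAC branch point in N25A
    with its branch adenosine 29 bp upstream of SA1, and adenosine-free
    filler elsewhere so it is the only SA1 branch-point candidate."""
    n25a = "CTAAC" + "GTGCTGTCGGTTGCCTGGCG"
    n25b = "GCCTGGTTGCTGTCGGCTGGTCGGC"
    return make_minigene("BASE", "ACGTACGTACGTACGTACGT", n25a, n25b, scaffold)


def novel_acceptor_positions(mg: Minigene, min_room: int = 6) -> list[int]:
    """Acceptor positions created by AG dinucleotides inside N25A/N25B.

    The acceptor is the base following the AG; candidates need ``min_room``
    nt of downstream sequence for a mappable junction.
    """
    out: list[int] = []
    for start, insert in ((mg.n25a_start, mg.n25a), (mg.n25b_start, mg.n25b)):
        idx = insert.find("AG")
        while idx != -1:
            pos = start + idx + 2
            if pos + min_room <= len(mg.full_seq):
                out.append(pos)
            idx = insert.find("AG", idx + 1)
    return sorted(out)


def _pyrimidine_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("C") + seq.count("T")) / len(seq)


def _candidate_acceptors(mg: Minigene) -> list[tuple[str, int]]:
    cands = [("SA1", mg.sa1_pos), ("SA2", mg.sa2_pos)]
    cands.extend(("NOVEL", p) for p in novel_acceptor_positions(mg))
    return cands


def _acceptor_logweights(mg: Minigene, params: SpliceModelParams) -> dict:
    """Per-acceptor (WT, K700E) log-weights, sharing one BP scan per acceptor."""
    baselines = {"SA1": 0.0, "SA2": params.sa2_bonus, "NOVEL": params.novel_penalty}
    out = {}
    for label, pos in _candidate_acceptors(mg):
        key = label if label != "NOVEL" else f"NOVEL@{pos}"
        ppt = _pyrimidine_fraction(mg.full_seq[max(0, pos - 20) : pos])
        base = baselines[label] + params.beta_ppt * ppt
        if params.beta_bp == 0.0:
            out[key] = (base, base)
            continue
        upstream = mg.full_seq[:pos]
        cand_wt = predict_bp(upstream, params.bp_search_window, params.duplex, WT)
        cand_k = predict_bp(upstream, params.bp_search_window, params.duplex, K700E)
        dg_wt = cand_wt.delta_g if cand_wt is not None else 0.0
        dg_k = cand_k.delta_g if cand_k is not None else 0.0
        out[key] = (base - params.beta_bp * dg_wt, base - params.beta_bp * dg_k)
    return out


def acceptor_weights(mg: Minigene, condition: str, params: SpliceModelParams) -> dict:
    """Probability of each candidate acceptor (SA1, SA2, NOVEL@pos) for one
    minigene under the given condition; probabilities sum to 1."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    idx = 0 if condition == WT else 1
    logw = {k: v[idx] for k, v in _acceptor_logweights(mg, params).items()}
    mx = max(logw.values())
    w = {k: math.exp(v - mx) for k, v in logw.items()}
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def simulate_transcripts(
    library: Sequence[Minigene],
    condition: str,
    params: SpliceModelParams,
    depth: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample transcripts per minigene from the acceptor-competition model.

    Per-minigene depth is Poisson with mean ``depth``; acceptor counts are a
    multinomial draw from :func:`acceptor_weights`.  Returns a truth table
    with columns (minigene_id, condition, acceptor_class, acceptor_pos,
    count); rows with zero counts are omitted.
    """
    if len(library) == 0:
        raise ValueError("library must be nonempty")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    idx = 0 if condition == WT else 1
    rows = []
    for mg in library:
        n = int(rng.poisson(depth))
        if n == 0:
            continue
        logw = _acceptor_logweights(mg, params)
        keys = list(logw)
        lw = np.array([logw[k][idx] for k in keys])
        p = np.exp(lw - lw.max())
        p /= p.sum()
        counts = rng.multinomial(n, p)
        for key, c in zip(keys, counts):
            if c == 0:
                continue
            if key.startswith("NOVEL@"):
                cls, pos = "NOVEL", int(key.split("@")[1])
            else:
                cls, pos = key, mg.sa1_pos if key == "SA1" else mg.sa2_pos
            rows.append((mg.id, condition, cls, pos, int(c)))
    return pd.DataFrame(
        rows, columns=["minigene_id", "condition", "acceptor_class", "acceptor_pos", "count"]
    )


def _spliced_isoform(mg: Minigene, acceptor_pos: int) -> str:
    return mg.full_seq[: mg.donor_pos] + mg.full_seq[acceptor_pos:]


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    k = rng.binomial(len(seq), error_rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def emit_reads(
    truth: pd.DataFrame,
    library: Sequence[Minigene],
    r1_path: str | Path,
    r2_path: str | Path,
    sidecar_path: str | Path,
    read_len: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
    min_flank: int = 15,
) -> int:
    """Write one paired read per transcript plus a read-level truth sidecar.

    R1 is drawn from the spliced isoform, centred on the exon1/acceptor
    junction; R2 starts at the 20-bp barcode.  Substitution errors are i.i.d.
    at ``error_rate``.  Returns the number of read pairs written.
    """
    by_id = {mg.id: mg for mg in library}
    if read_len < 2 * min_flank:
        raise ValueError(f"read_len must be >= {2 * min_flank} to span the junction")
    rng = np.random.default_rng(seed)
    left = read_len // 2
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, open(sidecar_path, "w") as fs:
        fs.write("read_id\tminigene_id\tacceptor_class\tacceptor_pos\n")
        qual = "I" * read_len
        for row in truth.itertuples(index=False):
            mg = by_id[row.minigene_id]
            if mg.donor_pos < left:
                raise ValueError("read_len too long for exon 1; junction flank escapes read")
            iso = _spliced_isoform(mg, int(row.acceptor_pos))
            start = mg.donor_pos - left
            r1 = iso[start : start + read_len]
            if len(r1) < read_len:
                raise ValueError("read_len too long for the spliced isoform")
            bc_iso = mg.barcode_start - (int(row.acceptor_pos) - mg.donor_pos)
            r2 = iso[bc_iso : bc_iso + read_len]
            if len(r2) < read_len:
                raise ValueError("read_len exceeds sequence downstream of the barcode")
            for _ in range(int(row.count)):
                rid = f"r{n:09d}"
                a = _mutate(r1, rng, error_rate) if error_rate > 0 else r1
                b = _mutate(r2, rng, error_rate) if error_rate > 0 else r2
                f1.write(f"@{rid}/1\n{a}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{b}\n+\n{qual}\n")
                fs.write(f"{rid}\t{row.minigene_id}\t{row.acceptor_class}\t{row.acceptor_pos}\n")
                n += 1
    return n


def write_library_tsv(library: Iterable[Minigene], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.id, m.barcode, m.n25a, m.n25b, m.full_seq, m.sa1_pos, m.sa2_pos,
             m.donor_pos, m.n25a_start, m.n25b_start, m.barcode_start)
            for m in library
        ],
        columns=["id", "barcode", "n25a", "n25b", "full_seq", "sa1_pos", "sa2_pos",
                 "donor_pos", "n25a_start", "n25b_start", "barcode_start"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[Minigene]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return [
        Minigene(
            id=r.id, barcode=r.barcode, n25a=r.n25a, n25b=r.n25b, full_seq=r.full_seq,
            sa1_pos=int(r.sa1_pos), sa2_pos=int(r.sa2_pos), donor_pos=int(r.donor_pos),
            n25a_start=int(r.n25a_start), n25b_start=int(r.n25b_start),
            barcode_start=int(r.barcode_start),
        )
        for r in df.itertuples(index=False)
    ]
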