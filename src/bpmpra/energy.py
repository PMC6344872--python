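"""U2 snRNA-branch point duplex free-energy model and heuristic BP prediction.

The branch point (BP) region of an intron base-pairs with the U2 snRNA
branch-point-recognition sequence 5'-GUAGUA-3', leaving the nucleophilic
branch adenosine bulged out of the helix.  A BP candidate is represented as a
9-mer window with the branch adenosine at index 4 (the fifth base); positions
are numbered relative to that adenosine, so the window spans -4..+4.

Pairing register (antiparallel)::

    intron 5'- b(-4) b(-3) b(-2) b(-1) [A] b(+1) -3'
    U2     3'-  U     G     A     U         G    -5'   (5'-GUAGUA-3')

The fully paired configuration therefore requires T at -2, A at -1, C/T at
-3 and +1 (G-C Watson-Crick or G.T wobble) -- i.e. exactly the canonical
YTAAY branch-point core.  Stability is scored with a nearest-neighbour
stacking model: consecutive paired positions contribute a stack term from a
packaged table of RNA stacking free energies, the bulged adenosine costs a
fixed bulge penalty, and each unpaired position costs a position-specific
mismatch penalty.  The total is clamped at 0 kcal/mol (a window that cannot
form a stabilising duplex does not bind).

The mutant (K700E) mode models the single mechanistic effect of mutant
SF3B1: tolerance of non-canonical bases immediately 5' of the branch
adenosine.  The -1 mismatch penalty is scaled by lambda in [0, 1] before
the clamp (lambda = 1 reproduces the wild type), so the bulk of the mutant
stabilisation is realised only where a duplex actually forms; in addition a
small strict-preference margin eps * (1 - lambda) is subtracted for any
window whose -1 base is not A, so that mutant stabilisation of -1 variants
is strict for every such window::

    dG_K700E = min(E(window, lambda), 0) - eps * (1 - lambda) * [b(-1) != A]
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DuplexParams",
    "BPCandidate",
    "DEFAULT_DUPLEX",
    "U2_PARTNER",
    "duplex_energy",
    "predict_bp",
    "compare_energies",
]

_DNA2RNA = str.maketrans("T", "U")
_VALID = set("ACGT")

#: U2 partner base (RNA alphabet) for each paired intron position relative to
#: the bulged branch adenosine (position 0 itself is unpaired).
U2_PARTNER = {-4: "U", -3: "G", -2: "A", -1: "U", 1: "G"}

#: Paired positions in 5'->3' order along the intron strand.
PAIR_ORDER = (-4, -3, -2, -1, 1)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

# Watson-Crick nearest-neighbour stacks, 5'XY3'/3'WZ5', kcal/mol at 37 C
# (Turner-style RNA parameters; the ten unique symmetric entries).
_WC_STACKS = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}


@dataclass
class DuplexParams:
    """Parameters of the U2-BP duplex model.

    ``stacks`` maps (top dinucleotide, bottom dinucleotide) of a helix step
    (both 5'->3' top / 3'->5' bottom, RNA alphabet) to a stacking free energy
    in kcal/mol; steps involving a wobble pair fall back to
    ``wobble_stack``.  ``mismatch_penalty`` is a per-position destabilisation
    (kcal/mol, >= 0) for an unpaired intron base, ``bulge_penalty`` is the
    cost of the bulged branch adenosine, and ``lambda_minus1`` scales the
    residual -1 mismatch penalty in K700E mode.
    """

    stacks: dict = field(default_factory=lambda: dict(_WC_STACKS))
    wobble_stack: float = -0.50
    mismatch_penalty: dict = field(
        default_factory=lambda: {-4: 0.5, -3: 1.0, -2: 2.0, -1: 2.5, 1: 1.0}
    )
    # kept below the weakest bulge-closing stack plus the +1 mismatch penalty,
    # so that closing the helix across the bulged adenosine is always favourable
    bulge_penalty: float = 1.0
    lambda_minus1: float = 1.0
    # strict mutant-preference margin for -1 variants (kcal/mol); keeps
    # dG_K700E < dG_WT even for windows clamped to 0 in both modes
    strict_margin: float = 0.1
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_minus1 <= 1.0:
            raise ValueError("lambda_minus1 must lie in [0, 1]")
        if any(v > 0 for v in self.stacks.values()) or self.wobble_stack > 0:
            raise ValueError("stack energies must be <= 0")
        if any(v < 0 for v in self.mismatch_penalty.values()):
            raise ValueError("mismatch penalties must be >= 0")


DEFAULT_DUPLEX = DuplexParams()


@dataclass(frozen=True)
class BPCandidate:
    """A branch-point candidate: a 9-mer with the branch A at the fifth base."""

    window: str
    position: int  # 0-based coordinate of the branch adenosine
    delta_g: float  # kcal/mol, clamped at 0
    offset_to_acceptor: int  # negative; position - acceptor position


def _paired(base: str, pos: int) -> bool:
    """Can the intron base pair with its U2 partner at this position?

    Wobble pairs are accepted except at -1: the -1 position must present the
    canonical adenosine to engage, mirroring its strict conservation in the
    YTAAY consensus (G at -1 is a bona fide -1 variant, not a wobble pair).
    """
    b = base.translate(_DNA2RNA)
    u = U2_PARTNER[pos]
    if (b, u) in _WC:
        return True
    return pos != -1 and (b, u) in _WOBBLE


def _stack(b1: str, u1: str, b2: str, u2: str, params: DuplexParams) -> float:
    if ("G" in (b1, u1) and "U" in (b1, u1) and (b1, u1) not in _WC) or (
        "G" in (b2, u2) and "U" in (b2, u2) and (b2, u2) not in _WC
    ):
        return params.wobble_stack
    key = (b1 + b2, u1 + u2)
    if key in params.stacks:
        return params.stacks[key]
    alt = ((u1 + u2)[::-1], (b1 + b2)[::-1])
    return params.stacks[alt]


def _wt_energy(window: str, params: DuplexParams) -> float:
    """Unclamped duplex energy of a 9-mer window with full (WT) penalties."""
    cached = params._cache.get(window)
    if cached is not None:
        return cached
    bases = {p: window[4 + p] for p in PAIR_ORDER}
    paired = {p: _paired(bases[p], p) for p in PAIR_ORDER}
    total = 0.0
    for p, mism in params.mismatch_penalty.items():
        if not paired[p]:
            total += mism
    for pa, pb in zip(PAIR_ORDER, PAIR_ORDER[1:]):
        if paired[pa] and paired[pb]:
            ba = bases[pa].translate(_DNA2RNA)
            bb = bases[pb].translate(_DNA2RNA)
            total += _stack(ba, U2_PARTNER[pa], bb, U2_PARTNER[pb], params)
    if paired[-1] and paired[1]:
        total += params.bulge_penalty  # 1-nt bulge between -1 and +1
    params._cache[window] = total
    return total


def duplex_energy(
    window: str, params: DuplexParams | None = None, mode: str = "WT"
) -> float:
    """Free energy (kcal/mol, <= 0) of the U2-BP duplex for one 9-mer window.

    ``mode`` is ``"WT"`` or ``"K700E"``; the branch base at index 4 is treated
    as bulged regardless of identity.
    """
    params = params if params is not None else DEFAULT_DUPLEX
    if len(window) != 9:
        raise ValueError(f"BP window must be a 9-mer, got {len(window)} nt")
    if not set(window) <= _VALID:
        raise ValueError(f"non-ACGT character in window {window!r}")
    if mode not in ("WT", "K700E"):
        raise ValueError(f"unknown mode {mode!r}")
    e_wt = _wt_energy(window, params)
    if mode == "WT" or window[3] == "A":
        return min(e_wt, 0.0)
    relief = 1.0 - params.lambda_minus1
    e_mut = e_wt - relief * params.mismatch_penalty[-1]
    return min(e_mut, 0.0) - relief * params.strict_margin


def predict_bp(
    upstream_seq: str,
    acceptor_offset_window: tuple[int, int] = (-50, -10),
    params: DuplexParams | None = None,
    mode: str = "WT",
) -> BPCandidate | None:
    """Best (minimum-energy) branch-point candidate upstream of an acceptor.

    ``upstream_seq`` ends immediately 5' of the acceptor (the acceptor sits
    at ``len(upstream_seq)``).  All adenosine-centred 9-mers whose adenosine
    lies within ``acceptor_offset_window`` (offsets relative to the acceptor)
    are scored; ties break toward the acceptor-proximal position.  Returns
    ``None`` when the window holds no scorable adenosine.
    """
    params = params if params is not None else DEFAULT_DUPLEX
    lo, hi = acceptor_offset_window
    if lo > hi:
        raise ValueError("acceptor_offset_window must be (low, high)")
    n = len(upstream_seq)
    best: BPCandidate | None = None
    for off in range(hi, lo - 1, -1):  # proximal first; strict improvement wins
        idx = n + off
        if idx - 4 < 0 or idx + 5 > n or upstream_seq[idx] != "A":
            continue
        win = upstream_seq[idx - 4 : idx + 5]
        dg = duplex_energy(win, params, mode)
        if best is None or dg < best.delta_g:
            best = BPCandidate(window=win, position=idx, delta_g=dg, offset_to_acceptor=off)
    return best


def _energies(xs: Iterable) -> np.ndarray:
    vals = [x.delta_g if isinstance(x, BPCandidate) else float(x) for x in xs]
    return np.asarray(vals, dtype=float)


def compare_energies(
    set_a: Sequence, set_b: Sequence, labels: tuple[str, str] = ("A", "B")
) -> dict:
    """Compare two sets of BP duplex energies with a Wilcoxon rank-sum test.

    Accepts sequences of :class:`BPCandidate` or plain energies.  Returns the
    per-set means, the two-sided Mann-Whitney U statistic and p-value, and
    which set is less stable (higher mean free energy).
    """
    a, b = _energies(set_a), _energies(set_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both energy sets must be nonempty")
    stat, pvalue = stats.mannwhitneyu(a, b, alternative="two-sided")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    less_stable = labels[0] if mean_a > mean_b else labels[1]
    if mean_a == mean_b:
        less_stable = None
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "label_a": labels[0],
        "label_b": labels[1],
        "mean_a": mean_a,
        "mean_b": mean_b,
        "statistic": float(stat),
        "pvalue": float(pvalue),
        "less_stable": less_stable,
    }


def all_windows(center: str = "A") -> "itertools.product":
    """Iterate every 9-mer context with the given branch base fixed at index 4."""
    for ctx in itertools.product("ACGT", repeat=8):
        yield "".join(ctx[:4]) + center + "".join(ctx[4:])
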