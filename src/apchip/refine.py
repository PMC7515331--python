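"""Cluster validation, greedy trimming, and information-content ranking.

A cluster produced for a ZOOPS problem with q of t sequences carrying an
instance should hold between t - q (exclusive) and t (inclusive) l-mers.
Oversized clusters are trimmed to exactly t members by greedily growing
from the exemplar, at each step adding the l-mer with the largest summed
string similarity to the members already kept, where the similarity of two
l-mers is |LCS| / (|x| + |y| - |LCS|) with LCS the longest common
substring.

Valid clusters are summarised as position weight matrices and ranked by
information content — the relative entropy (in bits) of the PWM columns
against the background base composition — and the top model is reported as
the motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence, TextIO

import numpy as np

from .candidates import ClusterSubset
from .dataset import LMerOccurrence, encode

__all__ = [
    "SizeVerdict",
    "MotifModel",
    "validate_size",
    "string_similarity",
    "greedy_trim",
    "information_content",
    "consensus_from_pwm",
    "rank_and_report",
    "write_meme",
]

_BASES = "ACGT"

# IUPAC degenerate codes keyed by the sorted set of bases they cover
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AG": "R", "CT": "Y", "CG": "S", "AT": "W", "GT": "K", "AC": "M",
    "CGT": "B", "AGT": "D", "ACT": "H", "ACG": "V", "ACGT": "N",
}


class SizeVerdict(Enum):
    INVALID = "invalid"
    VALID = "valid"
    OVERSIZED = "oversized"


def validate_size(cluster: ClusterSubset, t: int, q: int) -> SizeVerdict:
    """Classify a cluster by the size interval (t - q, t].

    Sizes of at most t - q cannot carry q instances once background leakage
    is accounted for; sizes above t exceed one-per-sequence occupancy and
    must be trimmed.
    """
    m = len(cluster.members)
    if m <= t - q:
        return SizeVerdict.INVALID
    if m <= t:
        return SizeVerdict.VALID
    return SizeVerdict.OVERSIZED


def _lcs_length(a: str, b: str) -> int:
    """Longest common substring length, O(|a|*|b|) rolling DP."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best = v
        prev = cur
    return best


def _overlap_length(a: str, b: str) -> int:
    """Largest k with a suffix of one string equal to a prefix of the other."""
    best = 0
    for x, y in ((a, b), (b, a)):
        for k in range(min(len(x), len(y)), 0, -1):
            if x[-k:] == y[:k]:
                best = max(best, k)
                break
    return best


def string_similarity(a: str, b: str, mode: Literal["lcs", "overlap"] = "lcs") -> float:
    """Jaccard-style similarity len(a,b) / (|a| + |b| - len(a,b)).

    ``len`` is the longest common substring by default; identical strings
    score 1, strings sharing no character score 0.
    """
    n = _lcs_length(a, b) if mode == "lcs" else _overlap_length(a, b)
    denom = len(a) + len(b) - n
    return n / denom if denom else 1.0


def greedy_trim(
    cluster: ClusterSubset,
    exemplar: LMerOccurrence,
    t: int,
    sim_mode: Literal["lcs", "overlap"] = "lcs",
) -> ClusterSubset:
    """Select exactly t members, growing greedily from the exemplar.

    Each step adds the member maximizing the summed string similarity to
    the already-selected set; ties break by (seq_index, offset).  The
    exemplar is always retained.
    """
    if exemplar not in cluster.members:
        raise ValueError("exemplar is not a member of the cluster")
    if len(cluster.members) <= t:
        return cluster
    cache: dict[tuple[str, str], float] = {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = string_similarity(a, b, sim_mode)
        return cache[key]

    selected = [exemplar]
    remaining = [p for p in cluster.members if p != exemplar]
    scores = {p: 0.0 for p in remaining}
    last = exemplar
    while len(selected) < t:
        for p in remaining:
            scores[p] += sim(p.text, last.text)
        best = max(remaining, key=lambda p: (scores[p], -p.seq_index, -p.offset))
        selected.append(best)
        remaining.remove(best)
        del scores[best]
        last = best
    selected.sort(key=lambda p: (p.seq_index, p.offset))
    return ClusterSubset(reference=exemplar, members=selected)


@dataclass
class MotifModel:
    """A motif summarised as PWM + consensus + information content."""

    pwm: np.ndarray  # (4, l) column-stochastic, rows in ACGT order
    background: np.ndarray  # (4,) base frequencies
    consensus: str
    ic: float  # bits
    occurrences: list[LMerOccurrence]
    exemplar: LMerOccurrence | None = None

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def support(self) -> int:
        return len(self.occurrences)


def consensus_from_pwm(
    pwm: np.ndarray,
    major_freq: float = 0.5,
    major_margin: float = 0.15,
    degenerate_freq: float = 0.35,
) -> str:
    """Per-column IUPAC consensus.

    A single base is emitted when its frequency reaches ``major_freq`` and
    leads the runner-up by ``major_margin``; otherwise the IUPAC code of all
    bases at or above ``degenerate_freq`` (falling back to the top base when
    none qualifies).
    """
    out = []
    for col in pwm.T:
        order = np.argsort(-col, kind="stable")
        top, second = col[order[0]], col[order[1]]
        if top >= major_freq and top - second >= major_margin:
            out.append(_BASES[order[0]])
            continue
        bases = sorted(_BASES[w] for w in range(4) if col[w] >= degenerate_freq)
        if not bases:
            bases = [_BASES[order[0]]]
        out.append(_IUPAC["".join(bases)])
    return "".join(out)


def information_content(
    cluster: ClusterSubset,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.0,
) -> MotifModel:
    """Build the PWM of a cluster and score it by relative entropy.

    IC = sum_m sum_w p_{w,m} log2(p_{w,m} / p_{w,0}) with 0*log 0 = 0.
    ``pseudocount`` adds Laplace-style mass per base per column before
    normalising; with the default 0 a fully conserved column contributes
    exactly log2(1/p_{w,0}) bits.
    """
    if not cluster.members:
        raise ValueError("cluster is empty")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    bg = bg / bg.sum()
    codes = np.stack([encode(p.text) for p in cluster.members])
    l = codes.shape[1]
    counts = np.zeros((4, l))
    for w in range(4):
        counts[w] = (codes == w).sum(axis=0)
    counts += pseudocount
    pwm = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pwm > 0, pwm * np.log2(pwm / bg[:, None]), 0.0)
    ic = float(terms.sum())
    return MotifModel(
        pwm=pwm,
        background=bg,
        consensus=consensus_from_pwm(pwm),
        ic=ic,
        occurrences=list(cluster.members),
        exemplar=cluster.reference,
    )


def rank_and_report(models: list[MotifModel], top_n: int | None = None) -> list[MotifModel]:
    """Sort by IC descending; break ties by lexicographic consensus.

    Models sharing a consensus string collapse to the highest-IC instance.
    An empty input yields an empty report.
    """
    ranked = sorted(models, key=lambda mo: (-mo.ic, mo.consensus))
    seen: set[str] = set()
    out = []
    for mo in ranked:
        if mo.consensus in seen:
            continue
        seen.add(mo.consensus)
        out.append(mo)
    return out if top_n is None else out[:top_n]


def write_meme(models: list[MotifModel], handle: TextIO, names: list[str] | None = None) -> None:
    """Write PWMs in MEME minimal motif format."""
    handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
    if models:
        bg = models[0].background
        handle.write("Background letter frequencies\n")
        handle.write(" ".join(f"{b} {f:.5f}" for b, f in zip(_BASES, bg)) + "\n\n")
    for rank, mo in enumerate(models, start=1):
        name = names[rank - 1] if names else mo.consensus
        handle.write(f"MOTIF {name} APCHIP-{rank}\n")
        handle.write(
            f"letter-probability matrix: alength= 4 w= {mo.length} "
            f"nsites= {mo.support} E= 0\n"
        )
        for col in mo.pwm.T:
            handle.write(" " + " ".join(f"{v:8.6f}" for v in col) + "\n")
        handle.write("\n")
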