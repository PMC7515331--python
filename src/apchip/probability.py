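"""Hamming-neighborhood probability calculus for planted (l, d) motif search.

All quantities assume an i.i.d. uniform background over {A, C, G, T}, so the
per-position mismatch probability between two unrelated l-mers is 3/4. Motif
instances are modelled as copies of a common motif in which d designated
positions were redrawn uniformly from the four bases, making the realised
per-instance mutation count Binomial(d, 3/4).

Three probabilities drive the algorithm's thresholds:

* ``background_neighborhood_prob`` -- chance two random l-mers lie within
  Hamming distance k (controls how many background l-mers leak into a
  cluster subset);
* ``motif_pair_prob`` -- chance two instances of the same motif lie within
  k (controls how many true instances the subset captures);
* ``occurrence_frequency`` -- chance a random l-mer position in a sequence
  carries a degenerate copy of a given motif (sets the per-sequence hit
  threshold used by the candidate filter).

``motif_pair_prob`` ships two models.  The default ``"overlap"`` model scores a pair
of instances at mutation distances (alpha, beta) from the motif as "within
k" whenever their mutated position sets overlap in more than
floor((alpha+beta-k)/2) places -- a hypergeometric approximation that treats
overlapping mutations as always cancelling.  The ``"exact"`` model
additionally conditions on whether the redrawn characters at overlapping
positions agree (probability 1/3 per overlap given both positions actually
mutated).  The approximation is slightly conservative (e.g. 0.7414 vs the
exact 0.7623 at l=18, d=5, k=7) but is what published threshold tables for
this method tabulate, so it is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, floor
from typing import Literal

__all__ = [
    "MotifProblem",
    "ThresholdReport",
    "background_neighborhood_prob",
    "motif_pair_prob",
    "choose_k",
    "occurrence_frequency",
    "instance_difficulty_p2d",
    "threshold_report",
]


@dataclass(frozen=True)
class MotifProblem:
    """A planted (l, d) motif search instance.

    Parameters
    ----------
    l : motif length in bases.
    d : maximum number of mutated positions per instance.
    t : number of sequences in the dataset.
    n : sequence length in bases (for unequal-length real data, a nominal
        length; per-sequence lengths are used downstream where it matters).
    q : minimum number of sequences carrying an instance.  Exactly one of
        ``q`` / ``alpha_ratio`` may be given; the other is derived.
    alpha_ratio : q / t, the fraction of sequences carrying an instance.
    """

    l: int
    d: int
    t: int
    n: int
    q: int = 0
    alpha_ratio: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (0 <= self.d < self.l < self.n):
            raise ValueError(f"need 0 <= d < l < n, got d={self.d}, l={self.l}, n={self.n}")
        if self.t < 1:
            raise ValueError("t must be positive")
        if (self.q > 0) == (self.alpha_ratio > 0):
            raise ValueError("give exactly one of q or alpha_ratio")
        if self.q == 0:
            object.__setattr__(self, "q", int(round(self.alpha_ratio * self.t)))
        object.__setattr__(self, "alpha_ratio", self.q / self.t)
        if not (0 < self.q <= self.t):
            raise ValueError(f"need 0 < q <= t, got q={self.q}, t={self.t}")

    @property
    def h(self) -> int:
        """Number of reference sequences guaranteeing one carries an instance."""
        return self.t - self.q + 1


def _check_lk(l: int, k: int) -> None:
    if l < 0 or k < 0:
        raise ValueError(f"l and k must be non-negative, got l={l}, k={k}")
    if k > l:
        raise ValueError(f"radius k={k} exceeds l-mer length l={l}")


def background_neighborhood_prob(l: int, k: int) -> float:
    """P(d_H(x1, x2) <= k) for two i.i.d. uniform random l-mers.

    Exact rational evaluation of the binomial tail
    sum_{i=0..k} C(l,i) (3/4)^i (1/4)^(l-i), returned as a float.
    """
    _check_lk(l, k)
    total = sum(comb(l, i) * 3**i for i in range(k + 1))
    return float(Fraction(total, 4**l))


def _overlap_conditional(l: int, a: int, b: int, k: int) -> Fraction:
    """P(d_H(m1,m2) <= k | alpha=a, beta=b), hypergeometric-overlap model."""
    if a + b <= k:
        return Fraction(1)
    lo = floor((a + b - k) / 2) + 1
    num = sum(comb(a, i) * comb(l - a, b - i) for i in range(lo, min(a, b) + 1))
    return Fraction(num, comb(l, b))


def _exact_conditional(l: int, a: int, b: int, k: int) -> Fraction:
    """P(d_H(m1,m2) <= k | alpha=a, beta=b), exact pair-distance law.

    Overlap count i of the two realised mutation sets is hypergeometric;
    each overlapping position carries equal characters with probability 1/3
    (both were redrawn off the motif base), so the pair distance is
    a + b - i - j with j ~ Binomial(i, 1/3).
    """
    total = Fraction(0)
    for i in range(min(a, b) + 1):
        hyp = Fraction(comb(a, i) * comb(l - a, b - i), comb(l, b))
        for j in range(i + 1):
            if a + b - i - j <= k:
                total += hyp * comb(i, j) * Fraction(1, 3) ** j * Fraction(2, 3) ** (i - j)
    return total


def motif_pair_prob(
    l: int, d: int, k: int, model: Literal["overlap", "exact"] = "overlap"
) -> float:
    """P(d_H(m1, m2) <= k) for two instances of the same (l, d) motif.

    Both instances have d designated positions redrawn uniformly over the
    four bases, so their realised mutation counts alpha, beta are i.i.d.
    Binomial(d, 3/4).  See the module docstring for the two models.
    """
    if d >= l:
        raise ValueError(f"need d < l, got d={d}, l={l}")
    if k < 0 or k > 2 * d:
        raise ValueError(
            f"radius k={k} outside [0, 2d]={2 * d}: two instances of one motif "
            "cannot be further apart than 2d"
        )
    conditional = _overlap_conditional if model == "overlap" else _exact_conditional
    total = Fraction(0)
    denom = Fraction(1, 4**d)
    for a in range(d + 1):
        wa = comb(d, a) * 3**a * denom
        for b in range(d + 1):
            wb = comb(d, b) * 3**b * denom
            total += wa * wb * conditional(l, a, b, k)
    return float(total)


def choose_k(l: int, d: int, pkmotif_floor: float = 0.7) -> int:
    """Smallest radius k in (d, 2d] with motif_pair_prob(l, d, k) >= floor.

    Falls back to 2d (where the probability is exactly 1) if no smaller k
    qualifies.  The floor trades instance capture (larger pk_motif) against
    background leakage (larger pk); 0.7 keeps the background neighborhood
    small while retaining most instances.
    """
    if d < 1:
        raise ValueError("need d >= 1 to have a non-trivial radius range")
    if not (0.0 < pkmotif_floor <= 1.0):
        raise ValueError(f"pkmotif_floor must be in (0, 1], got {pkmotif_floor}")
    for k in range(d + 1, 2 * d + 1):
        if motif_pair_prob(l, d, k) >= pkmotif_floor:
            return k
    return 2 * d


def occurrence_frequency(
    l: int,
    d: int,
    p_mut: float | None = None,
    mode: Literal["neighborhood", "literal"] = "neighborhood",
) -> float:
    """Probability a random l-mer is a degenerate occurrence of a given motif.

    The per-position mutation probability ``p_mut`` defaults to d/l, the
    expected per-position mutation rate of a planted instance.  Two readings
    of the published expression are available:

    * ``"neighborhood"`` (default): sum_i Binom(i; d, p_mut) * C(l,i) 3^i / 4^l
      -- the chance a uniform random l-mer sits at Hamming distance i of the
      motif, binomially weighted over the tolerated mutation counts.
    * ``"literal"``: sum_i Binom(i; d, p_mut) / (C(l,i) 3^i) -- the printed
      form read verbatim; its i=0 term is (1-p_mut)^d, which makes the
      downstream per-sequence hit threshold p_occf*(n-l+1) larger than any
      attainable hit count for typical parameters.
    """
    if d >= l:
        raise ValueError(f"need d < l, got d={d}, l={l}")
    if p_mut is None:
        p_mut = d / l
    if not (0.0 <= p_mut <= 1.0):
        raise ValueError(f"p_mut must be in [0, 1], got {p_mut}")
    total = 0.0
    for i in range(d + 1):
        w = comb(d, i) * p_mut**i * (1.0 - p_mut) ** (d - i)
        if mode == "literal":
            total += w / (comb(l, i) * 3**i)
        else:
            total += w * comb(l, i) * 3**i / 4.0**l
    return total


def instance_difficulty_p2d(l: int, d: int) -> float:
    """2d-neighborhood probability grading (l, d) instance difficulty.

    P(d_H(x1, x2) <= 2d) for random l-mers; instances with larger p2d are
    weaker (background l-mers mimic instances more often).
    """
    if 2 * d > l:
        raise ValueError(f"need 2d <= l, got d={d}, l={l}")
    return background_neighborhood_prob(l, 2 * d)


@dataclass(frozen=True)
class ThresholdReport:
    """Radius choice and the probability table behind it."""

    k: int
    pk_by_k: dict[int, float]
    pkmotif_by_k: dict[int, float]
    p_occf: float
    p2d: float


def threshold_report(
    problem: MotifProblem,
    pkmotif_floor: float = 0.7,
    p_mut: float | None = None,
    occf_mode: Literal["neighborhood", "literal"] = "neighborhood",
    k_override: int | None = None,
) -> ThresholdReport:
    """Evaluate pk / pk_motif over the admissible radius range and pick k."""
    l, d = problem.l, problem.d
    # the table spans d..2d for context; the admissible choice range is (d, 2d]
    ks = list(range(d, 2 * d + 1))
    pk_by_k = {k: background_neighborhood_prob(l, k) for k in ks}
    pkmotif_by_k = {k: motif_pair_prob(l, d, k) for k in ks}
    if k_override is not None:
        if not (d < k_override <= 2 * d):
            raise ValueError(f"k override {k_override} outside (d, 2d] = ({d}, {2 * d}]")
        k = k_override
    else:
        k = choose_k(l, d, pkmotif_floor)
    return ThresholdReport(
        k=k,
        pk_by_k=pk_by_k,
        pkmotif_by_k=pkmotif_by_k,
        p_occf=occurrence_frequency(l, d, p_mut, occf_mode),
        p2d=instance_difficulty_p2d(l, d) if 2 * d <= l else float("nan"),
    )
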