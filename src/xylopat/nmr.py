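"""Ensemble statistics mirroring the NMR observables of acetylxylan.

Peak integration of HSQC spectra reports residue-type fractions (X, X2, X3,
X23); NOESY cross-peaks report which residue types sit next to each other.
Here both are emulated by direct counting over synthetic chains: type
fractions, triads around interior non-acetylated residues (X2–X–X2 etc.,
read non-reducing -> reducing), and ordered acetylated/non-acetylated
neighbor-pair counts, whose Ac–Ac and nonAc–nonAc cells are empty for a
strictly alternating decoration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .chain import Glca, XylanChain

__all__ = [
    "CompositionEstimate",
    "TriadCounts",
    "AdjacencyStats",
    "residue_type_fractions",
    "triad_counts",
    "adjacency_counts",
    "bernoulli_triads_closed_form",
    "ensemble_report",
]

TRIAD_KEYS = ("X2-X-X2", "X2-X-X3", "X3-X-X2", "X3-X-X3")
PAIR_KEYS = ("Ac-Ac", "Ac-nonAc", "nonAc-Ac", "nonAc-nonAc")


@dataclass(frozen=True)
class CompositionEstimate:
    """Residue-type percentages (0–100 scale) over an ensemble."""

    pct_X: float
    pct_X2: float
    pct_X3: float
    pct_X23: float
    n_residues: int

    def as_dict(self) -> dict[str, float]:
        return {
            "X": self.pct_X,
            "X2": self.pct_X2,
            "X3": self.pct_X3,
            "X23": self.pct_X23,
        }


@dataclass(frozen=True)
class TriadCounts:
    """Neighbor-type triads around interior non-acetylated residues.

    ``counts`` holds the four X2/X3 permutations; triads whose neighbors
    involve X23, a GlcA-bearing residue, or another non-acetylated residue
    land in ``other`` (experimentally those species were too weak or
    overlapped to assign).  ``total`` is the number of interior X scanned.
    """

    counts: dict[str, int]
    other: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.other


@dataclass(frozen=True)
class AdjacencyStats:
    """Ordered neighbor-pair counts over every backbone bond.

    Pairs are read non-reducing -> reducing: the first member of the pair is
    the residue closer to the non-reducing end.
    """

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, key: str) -> float:
        return self.counts[key] / self.total if self.total else 0.0


def residue_type_fractions(ensemble: Sequence[XylanChain]) -> CompositionEstimate:
    """Type percentages by direct counting (the HSQC-integration analogue)."""
    n = {"X": 0, "X2": 0, "X3": 0, "X23": 0}
    total = 0
    for chain in ensemble:
        for res in chain:
            n[res.residue_type] += 1
            total += 1
    if total == 0:
        raise ValueError("empty ensemble")
    pct = {k: 100.0 * v / total for k, v in n.items()}
    return CompositionEstimate(
        pct_X=pct["X"], pct_X2=pct["X2"], pct_X3=pct["X3"], pct_X23=pct["X23"],
        n_residues=total,
    )


def triad_counts(ensemble: Sequence[XylanChain]) -> TriadCounts:
    """Classify every interior non-acetylated residue by its two neighbors.

    The triad label reads non-reducing -> reducing: for center position i,
    the left symbol is residue i+1 and the right symbol residue i−1.  Chain
    ends are excluded (no interior environment).
    """
    counts = {k: 0 for k in TRIAD_KEYS}
    other = 0
    for chain in ensemble:
        for i in range(2, chain.dp):
            center = chain.residue(i)
            if center.acetylated:
                continue
            left, right = chain.residue(i + 1), chain.residue(i - 1)
            if any(r.glca is not Glca.NONE for r in (left, center, right)):
                other += 1
                continue
            lt, rt = left.residue_type, right.residue_type
            key = f"{lt}-X-{rt}"
            if lt in ("X2", "X3") and rt in ("X2", "X3"):
                counts[key] += 1
            else:
                other += 1
    return TriadCounts(counts=counts, other=other)


def adjacency_counts(ensemble: Sequence[XylanChain]) -> AdjacencyStats:
    """Tally ordered acetylated/non-acetylated pairs across every bond."""
    counts = {k: 0 for k in PAIR_KEYS}
    for chain in ensemble:
        for i in range(1, chain.dp):
            lo, hi = chain.residue(i), chain.residue(i + 1)
            a = "Ac" if hi.acetylated else "nonAc"   # non-reducing side first
            b = "Ac" if lo.acetylated else "nonAc"
            counts[f"{a}-{b}"] += 1
    return AdjacencyStats(counts=counts)


def bernoulli_triads_closed_form(
    p_X2: float, p_X3: float, p_X: float
) -> dict[str, float]:
    """Expected triad fractions for i.i.d. residue types.

    With residue types drawn independently, conditional on the center being
    an interior non-acetylated residue the two neighbors are independent, so

        P(a–X–b | center scanned) = p_a * p_b,   a, b in {X2, X3},

    and the remainder 1 − (p_X2 + p_X3)^2 falls in the ``other`` bucket.
    (The unconditional probability of the triad is p_a * p_X * p_b; the
    normalization over scanned positions divides out p_X.)
    """
    probs = {"X2": p_X2, "X3": p_X3, "X": p_X}
    if any(not 0.0 <= p <= 1.0 for p in probs.values()) or p_X2 + p_X3 + p_X > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0,1] and sum (with X23) to 1")
    out = {
        f"{a}-X-{b}": probs[a] * probs[b]
        for a, b in itertools.product(("X2", "X3"), repeat=2)
    }
    out["other"] = 1.0 - (p_X2 + p_X3) ** 2
    return out


def ensemble_report(ensemble: Sequence[XylanChain]) -> dict:
    """JSON-serializable summary: composition, triads, adjacency."""
    comp = residue_type_fractions(ensemble)
    tri = triad_counts(ensemble)
    adj = adjacency_counts(ensemble)
    return {
        "n_chains": len(ensemble),
        "composition_pct": comp.as_dict(),
        "n_residues": comp.n_residues,
        "triads": {**tri.counts, "other": tri.other, "total": tri.total},
        "adjacency": dict(adj.counts),
        "adjacency_fractions": {k: adj.fraction(k) for k in adj.counts},
    }
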