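"""Decorated xylan chains as ordered residue states.

A xylan backbone is a chain of β-(1,4)-linked xylopyranosyl residues.
Positions are 1-based and counted **from the reducing end** (position 1 is
the reducing-end residue; the literature's "−2 from the reducing end" of a
DP4 oligosaccharide is position 2 here, with the sign dropped).  Each
residue may be O-acetylated at O2 and/or O3 and may carry a (4-O-methyl)
glucuronosyl unit on O2.  Residue *type* (X, X2, X3, X23) is always derived
from the flags, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Iterator

__all__ = [
    "Glca",
    "ResidueState",
    "XylanChain",
    "chain_to_string",
    "chain_from_string",
    "ChainParseError",
]


class Glca(str, Enum):
    """Glucuronosyl decoration state of the O2 position."""

    NONE = "none"
    GLCA = "GlcA"
    MEGLCA = "MeGlcA"


@dataclass(frozen=True)
class ResidueState:
    """One xylosyl residue: position plus decoration flags.

    ``glca != NONE`` and ``ac2`` are mutually exclusive: both occupy the
    2-OH, so a 2-O-acetylated residue cannot also be glucuronosylated.
    """

    index: int
    ac2: bool = False
    ac3: bool = False
    glca: Glca = Glca.NONE

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.glca is not Glca.NONE and self.ac2:
            raise ValueError(
                f"residue {self.index}: GlcA and 2-O-acetyl both occupy O2 "
                "and cannot coexist"
            )

    @property
    def acetylated(self) -> bool:
        return self.ac2 or self.ac3

    @property
    def residue_type(self) -> str:
        """Derived NMR-style type label: X, X2, X3 or X23."""
        if self.ac2 and self.ac3:
            return "X23"
        if self.ac2:
            return "X2"
        if self.ac3:
            return "X3"
        return "X"

    def with_index(self, index: int) -> "ResidueState":
        return replace(self, index=index)


@dataclass(frozen=True)
class XylanChain:
    """An ordered xylan backbone, reducing end first (index 1)."""

    residues: tuple[ResidueState, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a xylan chain needs at least one residue (dp >= 1)")
        for pos, res in enumerate(self.residues, start=1):
            if res.index != pos:
                raise ValueError(
                    f"residue indices must be contiguous 1..dp; "
                    f"slot {pos} holds index {res.index}"
                )

    @classmethod
    def from_states(cls, states: Iterable[ResidueState]) -> "XylanChain":
        return cls(tuple(states))

    @property
    def dp(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> ResidueState:
        """Residue at 1-based position ``index`` from the reducing end."""
        if not 1 <= index <= self.dp:
            raise IndexError(f"position {index} outside 1..{self.dp}")
        return self.residues[index - 1]

    def __iter__(self) -> Iterator[ResidueState]:
        return iter(self.residues)

    def types(self) -> list[str]:
        return [r.residue_type for r in self.residues]

    @property
    def n_acetyl(self) -> int:
        return sum(r.ac2 + r.ac3 for r in self.residues)

    @property
    def n_glca(self) -> int:
        return sum(r.glca is not Glca.NONE for r in self.residues)


# ---------------------------------------------------------------------------
# text serialization
#
# Chains are written non-reducing -> reducing ("left to right toward the
# reducing end", the convention used when reading enzyme products), with the
# reducing-end token marked "(r)".  GlcA is a "g" suffix, MeGlcA "mg":
# e.g. "X3-Xg-X3-X(r)".

_TOKEN_RE = re.compile(r"^X(?P<ac>23|2|3)?(?P<glca>mg|g)?$")


class ChainParseError(ValueError):
    """Malformed chain string; carries the offending 1-based token offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"token {offset}: {message}")
        self.offset = offset


def _residue_token(res: ResidueState) -> str:
    tok = res.residue_type
    if res.glca is Glca.GLCA:
        tok += "g"
    elif res.glca is Glca.MEGLCA:
        tok += "mg"
    return tok


def chain_to_string(chain: XylanChain) -> str:
    tokens = [_residue_token(r) for r in reversed(chain.residues)]
    tokens[-1] += "(r)"
    return "-".join(tokens)


def _parse_token(tok: str, offset: int, index: int) -> ResidueState:
    m = _TOKEN_RE.match(tok)
    if m is None:
        raise ChainParseError(f"unrecognized residue token {tok!r}", offset)
    ac = m.group("ac") or ""
    glca = {None: Glca.NONE, "g": Glca.GLCA, "mg": Glca.MEGLCA}[m.group("glca")]
    try:
        return ResidueState(
            index=index, ac2="2" in ac, ac3="3" in ac, glca=glca
        )
    except ValueError as exc:  # e.g. X2g: O2 doubly occupied
        raise ChainParseError(str(exc), offset) from exc


def chain_from_string(text: str) -> XylanChain:
    text = text.strip()
    if not text:
        raise ChainParseError("empty chain string", 1)
    tokens = text.split("-")
    last = tokens[-1]
    if not last.endswith("(r)"):
        raise ChainParseError(
            "reducing-end token must carry the '(r)' marker", len(tokens)
        )
    tokens[-1] = last[: -len("(r)")]
    dp = len(tokens)
    # tokens run non-reducing -> reducing; residue 1 is the reducing end
    states = [
        _parse_token(tok, offset=i + 1, index=dp - i)
        for i, tok in enumerate(tokens)
    ]
    states.sort(key=lambda r: r.index)
    return XylanChain(tuple(states))
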