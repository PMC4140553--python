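"""Monoisotopic mass bookkeeping and MALDI m/z prediction for xylo-oligosaccharides.

Oligosaccharide neutral masses are assembled from residue increments
(anhydro units) plus one water for the free reducing/non-reducing termini:

    M = n_pentose * m(C5H8O4) + m(H2O) + n_acetyl * m(C2H2O)
        + n_hexuronate * m(C6H8O6) + n_methyl * m(CH2) [+ 2-AA label]

The 2-aminobenzoic acid (2-AA) label is attached by reductive amination of
the reducing end, a net gain of C7H7NO (label − H2O + H2).  MALDI spectra of
glycans in DHB are dominated by [M+Na]+, so the sodium adduct is the
default; peaks are compared nominally (nearest integer) because MALDI-ToF
ladders are read at unit resolution.

Elemental monoisotopic masses come from pyteomics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from pyteomics import mass as _pmass

from .chain import Glca
from .digest import Oligosaccharide

__all__ = [
    "MassTable",
    "DEFAULT_MASS_TABLE",
    "GlycanComposition",
    "SpectrumEntry",
    "neutral_mass",
    "adduct_mz",
    "nominal_mz",
    "spectrum_from_products",
    "y_ion_ladder",
    "match_peaks",
]

_ELECTRON = 0.00054857990907


def _formula(f: str) -> float:
    return float(_pmass.calculate_mass(formula=f))


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic mass increments (Da), fixed from elemental masses."""

    pentose: float = field(default_factory=lambda: _formula("C5H8O4"))
    water: float = field(default_factory=lambda: _formula("H2O"))
    acetyl: float = field(default_factory=lambda: _formula("C2H2O"))
    hexuronate: float = field(default_factory=lambda: _formula("C6H8O6"))
    methyl: float = field(default_factory=lambda: _formula("CH2"))
    label_2aa: float = field(default_factory=lambda: _formula("C7H7NO"))
    na_adduct: float = field(default_factory=lambda: _formula("Na") - _ELECTRON)
    h_adduct: float = field(default_factory=lambda: _formula("H") - _ELECTRON)


DEFAULT_MASS_TABLE = MassTable()

Label = Literal["none", "2AA"]
Adduct = Literal["M+Na", "M+H"]


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of mass-bearing units of one glycan species."""

    n_pentose: int
    n_acetyl: int = 0
    n_hexuronate: int = 0
    n_methyl: int = 0
    label: Label = "none"

    def __post_init__(self) -> None:
        if self.n_pentose < 1:
            raise ValueError("a glycan needs at least one pentose residue")
        if min(self.n_acetyl, self.n_hexuronate, self.n_methyl) < 0:
            raise ValueError("unit counts must be non-negative")
        if self.n_methyl > self.n_hexuronate:
            raise ValueError("n_methyl cannot exceed n_hexuronate (4-O-Me sits on GlcA)")

    @classmethod
    def from_oligo(cls, oligo: Oligosaccharide, label: Label = "none") -> "GlycanComposition":
        return cls(
            n_pentose=oligo.dp,
            n_acetyl=oligo.n_ac,
            n_hexuronate=oligo.n_glca,
            n_methyl=oligo.n_meglca,
            label=label,
        )

    def __str__(self) -> str:
        s = f"Xyl{self.n_pentose}"
        if self.n_acetyl:
            s += f"Ac{self.n_acetyl}"
        if self.n_hexuronate:
            me = self.n_methyl
            if me:
                s += f"MeGlcA{me}" + (f"GlcA{self.n_hexuronate - me}" if self.n_hexuronate > me else "")
            else:
                s += f"GlcA{self.n_hexuronate}"
        if self.label == "2AA":
            s += "-2AA"
        return s


def neutral_mass(comp: GlycanComposition, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Neutral monoisotopic mass (Da) of one composition."""
    m = (
        comp.n_pentose * table.pentose
        + table.water
        + comp.n_acetyl * table.acetyl
        + comp.n_hexuronate * table.hexuronate
        + comp.n_methyl * table.methyl
    )
    if comp.label == "2AA":
        m += table.label_2aa
    return m


def adduct_mz(mass: float, adduct: Adduct = "M+Na", table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Singly charged adduct m/z for a neutral mass."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if adduct == "M+Na":
        return mass + table.na_adduct
    if adduct == "M+H":
        return mass + table.h_adduct
    raise ValueError(f"unknown adduct {adduct!r}")


def nominal_mz(mz: float) -> int:
    """Nearest-integer m/z, for comparison with unit-resolution MALDI peaks."""
    return int(round(mz))


@dataclass(frozen=True)
class SpectrumEntry:
    mz: float
    relative_abundance: float
    composition: GlycanComposition


def spectrum_from_products(
    products: Sequence[Oligosaccharide],
    label: Label = "none",
    adduct: Adduct = "M+Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[SpectrumEntry]:
    """Count-based predicted spectrum of a product pool.

    Products are grouped by glycan composition; relative abundance is the
    count fraction (no ionization-efficiency model), so abundances sum to 1.
    Entries are sorted by m/z.
    """
    if not products:
        raise ValueError("no products to build a spectrum from")
    counts: Counter[GlycanComposition] = Counter(
        GlycanComposition.from_oligo(p, label) for p in products
    )
    n = sum(counts.values())
    entries = [
        SpectrumEntry(
            mz=adduct_mz(neutral_mass(comp, table), adduct, table),
            relative_abundance=c / n,
            composition=comp,
        )
        for comp, c in counts.items()
    ]
    return sorted(entries, key=lambda e: e.mz)


def y_ion_ladder(
    oligo: Oligosaccharide,
    label: Label = "2AA",
    adduct: Adduct = "M+Na",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[int, float]]:
    """Reducing-end-retaining (Y-type) fragment series of one product.

    Fragment k (k = 1..dp−1) keeps the first k residues from the reducing
    end with their decorations (and the reducing-end label).  Successive m/z
    differences are one pentose, or pentose+acetyl where the added residue
    is acetylated — the readout used to localize acetyl positions.
    """
    if oligo.dp < 2:
        raise ValueError("need dp >= 2 for a fragment ladder")
    out = []
    for k in range(1, oligo.dp):
        sub = oligo.residues[:k]
        comp = GlycanComposition(
            n_pentose=k,
            n_acetyl=sum(r.ac2 + r.ac3 for r in sub),
            n_hexuronate=sum(r.glca is not Glca.NONE for r in sub),
            n_methyl=sum(r.glca is Glca.MEGLCA for r in sub),
            label=label,
        )
        out.append((k, adduct_mz(neutral_mass(comp, table), adduct, table)))
    return out


def match_peaks(
    entries: Sequence[SpectrumEntry],
    peaks: Sequence[float],
    tol: float = 0.3,
) -> list[tuple[float, Optional[SpectrumEntry]]]:
    """Match observed peak m/z values to predicted entries within ``tol`` Da."""
    out: list[tuple[float, Optional[SpectrumEntry]]] = []
    for p in peaks:
        best = None
        best_d = tol
        for e in entries:
            d = abs(e.mz - p)
            if d <= best_d:
                best, best_d = e, d
        out.append((p, best))
    return out
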