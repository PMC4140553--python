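"""Endo-xylanase digestion under per-subsite decoration-tolerance rules.

Glycoside-hydrolase subsites are numbered from the scissile bond: −1 is the
residue whose anomeric carbon forms the cleaved glycosidic bond (toward the
non-reducing end), +1 the residue on the reducing side.  With chain
positions counted from the reducing end, bond ``b`` joins residue ``b+1``
(its C1) to residue ``b`` (its O4); subsite −n maps to residue ``b+n`` and
subsite +n to residue ``b−n+1``.  After cleavage the former −1 residue is
the new reducing end of the released (non-reducing-side) product.

Cleavage sites are evaluated once on the intact parent and cut
simultaneously.  Because every rule reads only the decorations of residues
around one bond — which digestion never alters — re-digesting any product
can expose no site that was not already permissible on the parent, so the
simultaneous cut equals iterated digestion to completion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chain import Glca, ResidueState, XylanChain
from .generate import SubstitutionSpec

__all__ = [
    "SubsiteRule",
    "EnzymeModel",
    "Oligosaccharide",
    "DigestResult",
    "permissible_sites",
    "digest",
    "ProductSummary",
    "product_summary",
    "even_dp_null_test",
    "get_enzyme",
    "CM_XYN10B",
    "EC_XYN30",
    "EC_XYN30_TOLERANT",
]


@dataclass(frozen=True)
class SubsiteRule:
    """Decoration tolerance of one subsite.

    ``allow_*`` flags reject residues carrying the corresponding
    decoration; ``require_o2_decoration`` additionally demands a 2-O
    substituent (acetyl or (Me)GlcA), the GH30-style −2 requirement.
    The predicate is total: every residue state maps to True or False.
    """

    allow_ac2: bool = True
    allow_ac3: bool = True
    allow_glca: bool = True
    require_o2_decoration: bool = False

    def allows(self, res: ResidueState) -> bool:
        if res.ac2 and not self.allow_ac2:
            return False
        if res.ac3 and not self.allow_ac3:
            return False
        if res.glca is not Glca.NONE and not self.allow_glca:
            return False
        if self.require_o2_decoration and not (res.ac2 or res.glca is not Glca.NONE):
            return False
        return True


UNRESTRICTED = SubsiteRule()
UNDECORATED_ONLY = SubsiteRule(allow_ac2=False, allow_ac3=False, allow_glca=False)


@dataclass(frozen=True)
class EnzymeModel:
    """A xylanase as a set of subsite tolerance rules.

    ``required_subsites`` must all be occupied by real residues for a bond
    to be cleavable; −1 is always required.
    """

    name: str
    subsite_rules: Mapping[int, SubsiteRule]
    required_subsites: frozenset[int]

    def __post_init__(self) -> None:
        if -1 not in self.required_subsites:
            raise ValueError("subsite -1 must be in required_subsites")

    def rule(self, subsite: int) -> SubsiteRule:
        return self.subsite_rules.get(subsite, UNRESTRICTED)


# GH10 endoxylanase from Cellvibrio mixtus: the −1 xylose packs both its
# 2-OH and 3-OH against the protein (no decorations tolerated); at −2 only a
# 3-O-acetyl fits (2-O substituents clash); +1 faces solvent.
CM_XYN10B = EnzymeModel(
    name="CmXyn10B",
    subsite_rules={
        -1: UNDECORATED_ONLY,
        -2: SubsiteRule(allow_ac2=False, allow_glca=False),
        +1: UNRESTRICTED,
    },
    required_subsites=frozenset({-2, -1, +1}),
)

# GH30 glucuronoxylanase from Erwinia chrysanthemi: strict preset demands a
# 2-O decoration (GlcA, MeGlcA, or — as acetylxylan cleavage shows — an
# acetyl) in the −2 pocket; the tolerant variant merely accepts it.
EC_XYN30 = EnzymeModel(
    name="EcXyn30",
    subsite_rules={
        -1: UNDECORATED_ONLY,
        -2: SubsiteRule(require_o2_decoration=True),
        +1: UNRESTRICTED,
    },
    required_subsites=frozenset({-2, -1, +1}),
)

EC_XYN30_TOLERANT = EnzymeModel(
    name="EcXyn30-tolerant",
    subsite_rules={-1: UNDECORATED_ONLY, -2: UNRESTRICTED, +1: UNRESTRICTED},
    required_subsites=frozenset({-2, -1, +1}),
)

_PRESETS = {
    "CmXyn10B": CM_XYN10B,
    "EcXyn30": EC_XYN30,
    "EcXyn30-tolerant": EC_XYN30_TOLERANT,
}


def get_enzyme(name: str) -> EnzymeModel:
    """Look up an enzyme preset by name (case-insensitive)."""
    for key, enz in _PRESETS.items():
        if key.lower() == name.lower():
            return enz
    raise KeyError(f"unknown enzyme preset {name!r}; have {sorted(_PRESETS)}")


def _subsite_residue(chain: XylanChain, bond: int, subsite: int) -> Optional[ResidueState]:
    """Residue occupying ``subsite`` relative to ``bond``, or None."""
    pos = bond - subsite if subsite < 0 else bond - subsite + 1
    if 1 <= pos <= chain.dp:
        return chain.residue(pos)
    return None


def permissible_sites(chain: XylanChain, enzyme: EnzymeModel) -> list[int]:
    """Bond indices (1..dp−1) cleavable by ``enzyme`` on ``chain``.

    A bond is permissible iff every required subsite is occupied by a real
    residue and every mapped residue satisfies its subsite rule.
    """
    if chain.dp < 2:
        raise ValueError("need dp >= 2 to have a cleavable bond")
    sites = []
    subsites = set(enzyme.required_subsites) | set(enzyme.subsite_rules)
    for bond in range(1, chain.dp):
        ok = True
        for s in subsites:
            res = _subsite_residue(chain, bond, s)
            if res is None:
                if s in enzyme.required_subsites:
                    ok = False
                    break
                continue
            if not enzyme.rule(s).allows(res):
                ok = False
                break
        if ok:
            sites.append(bond)
    return sites


@dataclass(frozen=True)
class Oligosaccharide:
    """A digestion product; residues keep their parent-chain positions."""

    residues: tuple[ResidueState, ...]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if not idx:
            raise ValueError("empty oligosaccharide")
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("parent positions must be contiguous")

    @property
    def dp(self) -> int:
        return len(self.residues)

    @property
    def n_ac(self) -> int:
        return sum(r.ac2 + r.ac3 for r in self.residues)

    @property
    def n_glca(self) -> int:
        return sum(r.glca is not Glca.NONE for r in self.residues)

    @property
    def n_meglca(self) -> int:
        return sum(r.glca is Glca.MEGLCA for r in self.residues)

    @property
    def parent_start(self) -> int:
        return self.residues[0].index

    @property
    def parent_end(self) -> int:
        return self.residues[-1].index

    def to_chain(self) -> XylanChain:
        """Re-index residues 1..dp (new reducing end = former −1 side)."""
        return XylanChain(
            tuple(r.with_index(i + 1) for i, r in enumerate(self.residues))
        )


@dataclass(frozen=True)
class DigestResult:
    products: tuple[Oligosaccharide, ...]
    cut_bonds: tuple[int, ...]
    parent_dp: int
    enzyme: str
    mode: Literal["complete", "partial"]
    site_prob: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if sum(p.dp for p in self.products) != self.parent_dp:
            raise ValueError("products do not conserve parent residues")


def digest(
    chain: XylanChain,
    enzyme: EnzymeModel,
    mode: Literal["complete", "partial"] = "complete",
    site_prob: Optional[float] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DigestResult:
    """Cleave ``chain`` at (a subset of) its permissible bonds.

    ``complete`` cuts every permissible bond (the high-enzyme-load limit);
    ``partial`` cuts each independently with probability ``site_prob`` (low
    load).  Decorations are never altered and residues are conserved.
    Products are ordered reducing -> non-reducing along the parent.
    """
    if chain.dp < 2:
        sites: list[int] = []
    else:
        sites = permissible_sites(chain, enzyme)
    if mode == "partial":
        if site_prob is None or not 0.0 <= site_prob <= 1.0:
            raise ValueError("partial digestion needs site_prob in [0, 1]")
        if rng is None:
            rng = np.random.default_rng(seed)
        sites = [b for b in sites if rng.random() < site_prob]
    elif mode != "complete":
        raise ValueError(f"unknown digestion mode {mode!r}")

    cuts = sorted(sites)
    bounds = [0, *cuts, chain.dp]
    products = tuple(
        Oligosaccharide(chain.residues[a:b]) for a, b in zip(bounds, bounds[1:])
    )
    return DigestResult(
        products=products,
        cut_bonds=tuple(cuts),
        parent_dp=chain.dp,
        enzyme=enzyme.name,
        mode=mode,
        site_prob=site_prob if mode == "partial" else None,
        seed=seed,
    )


@dataclass
class ProductSummary:
    """Counts of digestion products by (dp, n_ac, n_glca)."""

    table: pd.DataFrame  # columns: dp, n_ac, n_glca, count
    n_products: int

    @property
    def even_dp_fraction(self) -> float:
        even = self.table.loc[self.table["dp"] % 2 == 0, "count"].sum()
        return float(even) / float(self.n_products)

    def modal_acetyl_count(self, dp: int) -> int:
        """Most frequent acetyl count among products of this DP (ties -> smaller)."""
        sub = self.table[self.table["dp"] == dp]
        if sub.empty:
            raise KeyError(f"no products of dp={dp}")
        by_ac = sub.groupby("n_ac")["count"].sum()
        best = by_ac[by_ac == by_ac.max()]
        return int(best.index.min())


def product_summary(results: Sequence[DigestResult]) -> ProductSummary:
    """Tabulate products of one or more digests by (dp, n_ac, n_glca)."""
    counter: Counter[tuple[int, int, int]] = Counter()
    for res in results:
        for p in res.products:
            counter[(p.dp, p.n_ac, p.n_glca)] += 1
    if not counter:
        raise ValueError("no products to summarize")
    rows = [
        {"dp": k[0], "n_ac": k[1], "n_glca": k[2], "count": v}
        for k, v in sorted(counter.items())
    ]
    table = pd.DataFrame(rows)
    return ProductSummary(table=table, n_products=int(table["count"].sum()))


def even_dp_null_test(
    observed_even_fraction: float,
    null_spec: SubstitutionSpec,
    enzyme: EnzymeModel,
    n_sims: int = 500,
    seed: int = 0,
    n_chains: int = 10,
    mode: Literal["complete", "partial"] = "complete",
    site_prob: Optional[float] = None,
) -> float:
    """Monte-Carlo p-value for an excess of even-DP products over a null.

    Each simulation draws ``n_chains`` chains from ``null_spec``, digests
    them, and records the even-DP fraction of the *released* products
    (segments of chains that were actually cut; an intact chain is not a
    digestion product).  The add-one p-value is
    ``(1 + #{null >= observed}) / (n_sims + 1)``.  Small p means the
    observed preference for even product lengths is unlikely under the
    null decoration hypothesis (e.g. i.i.d. acetylation).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable p-value resolution")
    exceed = 0
    got_products = False
    for k in range(n_sims):
        rng = np.random.default_rng([seed, k])
        chains = [generate_chain_for_null(null_spec, rng) for _ in range(n_chains)]
        results = [
            digest(c, enzyme, mode=mode, site_prob=site_prob, rng=rng)
            for c in chains
        ]
        released = [r for r in results if r.cut_bonds]
        if not released:
            continue
        got_products = True
        if product_summary(released).even_dp_fraction >= observed_even_fraction:
            exceed += 1
    if not got_products:
        raise ValueError(
            "null simulations yielded no products; increase dp, n_chains, or "
            "choose a more permissive enzyme/site_prob"
        )
    return (1 + exceed) / (n_sims + 1)


def generate_chain_for_null(
    null_spec: SubstitutionSpec, rng: np.random.Generator
) -> XylanChain:
    """One null chain drawn from an externally supplied stream."""
    from .generate import add_glca, apply_migration, generate_chain

    chain = generate_chain(null_spec, rng)
    if null_spec.glca_mode != "none":
        chain = add_glca(chain, null_spec, rng)
    if null_spec.migration_p > 0:
        chain = apply_migration(chain, null_spec.migration_p, rng)
    return chain
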