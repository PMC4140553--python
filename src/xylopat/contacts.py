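"""Steric clash scoring and geometric hydrogen-bond detection on posed systems.

Clashes are heavy-atom pairs (xylan side, including substituents, against
cellulose) closer than a fraction of the summed van der Waals radii — the
common soft-contact criterion, default scale 0.7.

Hydrogen bonds are detected geometrically.  The models here carry no
hydrogens, so detection runs in heavy-atom-only mode: a candidate pair of
oxygens within ``d_max`` counts if at least one partner is a hydroxyl
(donor-capable); the mode label records the two oxygen identities
symmetrically (xylO2↔gluO6), so relabeling donor and acceptor leaves the
tally unchanged.  The ``angle_min`` criterion applies only when hydrogens
are present (never in the built models; kept for completeness).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cellulose import PosedSystem
from .helix import Conformation

__all__ = [
    "VDW_RADII",
    "ClashReport",
    "HBond",
    "clash_score",
    "detect_hbonds",
    "hbond_mode_tally",
]

VDW_RADII = {"C": 1.70, "O": 1.52, "N": 1.55}


@dataclass(frozen=True)
class ClashReport:
    n_clashes: int
    pairs: tuple[tuple[str, str, float], ...]  # (xylan atom, cellulose atom, Å)
    min_separation: float

    def __post_init__(self) -> None:
        if self.n_clashes != len(self.pairs):
            raise ValueError("n_clashes must equal the number of offending pairs")


def _atom_label(chain_id: str, a) -> str:
    return f"{chain_id}:{a.residue_index}:{a.name}"


def clash_score(posed: PosedSystem, scale: float = 0.7) -> ClashReport:
    """Count xylan↔cellulose heavy-atom pairs with separation below
    ``scale * (r_vdw_i + r_vdw_j)``.

    Monotone: lowering ``scale`` can only remove clashes.  An empty
    cellulose set scores zero.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    xat = posed.xylan.atoms
    cat = [a for ch in posed.cellulose for a in ch.atoms]
    cids = [ch.chain_id for ch in posed.cellulose for _ in ch.atoms]
    if not cat or not xat:
        return ClashReport(0, (), float("inf"))
    xc = np.array([a.xyz for a in xat])
    cc = np.array([a.xyz for a in cat])
    rmax = max(VDW_RADII.values())
    cutoff = scale * 2.0 * rmax
    tree = cKDTree(cc)
    pairs = []
    min_sep = float("inf")
    for i, close in enumerate(tree.query_ball_point(xc, r=cutoff + 0.1)):
        ri = VDW_RADII.get(xat[i].element, 1.7)
        for j in close:
            d = float(np.linalg.norm(xc[i] - cc[j]))
            min_sep = min(min_sep, d)
            rj = VDW_RADII.get(cat[j].element, 1.7)
            if d < scale * (ri + rj):
                pairs.append(
                    (
                        _atom_label(posed.xylan.chain_id, xat[i]),
                        _atom_label(cids[j], cat[j]),
                        d,
                    )
                )
    if min_sep == float("inf"):
        d = float(np.min(np.linalg.norm(xc[:, None, :] - cc[None, :, :], axis=2)))
        min_sep = d
    return ClashReport(len(pairs), tuple(pairs), min_sep)


@dataclass(frozen=True)
class HBond:
    donor: str      # atom label; in heavy-atom-only mode, the hydroxyl partner
    acceptor: str
    distance: float
    angle: Optional[float]
    mode: str       # e.g. "xylO2<->gluO6"


_ESTERIFIED = {"2": ("C2A",), "3": ("C3A",)}


def _oxygen_roles(conf: Conformation, side: str):
    """(atom, label, is_hydroxyl) for every oxygen able to hydrogen-bond.

    An O2/O3 bearing an acetyl (ester) or a GlcA attachment is excluded as a
    hydroxyl; glycosidic O4 and ring O5 are acceptor-only.  Terminal O4 (and
    the anomeric O1 of the reducing end, when present) are hydroxyls.
    """
    by_res: dict[int, set[str]] = {}
    for a in conf.atoms:
        by_res.setdefault(a.residue_index, set()).add(a.name)
    dp = conf.dp
    out = []
    for a in conf.atoms:
        if a.element != "O" or a.name.endswith("A"):  # skip carbonyl oxygens
            continue
        names = by_res[a.residue_index]
        if a.name == "O2":
            if "C2A" in names or "GA1" in names:
                continue  # esterified / glucuronosylated
            hydroxyl = True
        elif a.name == "O3":
            if "C3A" in names:
                continue
            hydroxyl = True
        elif a.name == "O6":
            hydroxyl = True
        elif a.name == "O4":
            hydroxyl = a.residue_index == dp  # interior O4 is glycosidic
        elif a.name == "O1":
            hydroxyl = True
        elif a.name == "O5":
            hydroxyl = False
        else:
            continue  # substituent marker oxygens (GA*) not tallied
        out.append((a, f"{side}{a.name}", hydroxyl))
    return out


def detect_hbonds(
    posed: PosedSystem,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    best_per_oxygen: bool = True,
) -> list[HBond]:
    """Geometric xylan↔cellulose hydrogen bonds on a posed system.

    Heavy-atom-only criterion: oxygen–oxygen distance ≤ ``d_max`` with at
    least one hydroxyl partner.  A hydroxyl carries a single proton, so by
    default each xylan oxygen is credited with at most one bond — its
    closest qualifying partner (``best_per_oxygen``).  Mode labels are
    symmetric under donor/acceptor relabeling.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    xyl = _oxygen_roles(posed.xylan, "xyl")
    glu = []
    for ch in posed.cellulose:
        glu.extend(
            (a, lbl, hyd, ch.chain_id) for a, lbl, hyd in _oxygen_roles(ch, "glu")
        )
    bonds = []
    for xa, xlbl, xhyd in xyl:
        candidates = []
        for ga, glbl, ghyd, cid in glu:
            if not (xhyd or ghyd):
                continue
            d = float(np.linalg.norm(xa.xyz - ga.xyz))
            if d <= d_max:
                donor, acceptor = (
                    (_atom_label(posed.xylan.chain_id, xa), _atom_label(cid, ga))
                    if xhyd
                    else (_atom_label(cid, ga), _atom_label(posed.xylan.chain_id, xa))
                )
                candidates.append(
                    HBond(
                        donor=donor,
                        acceptor=acceptor,
                        distance=d,
                        angle=None,
                        mode=f"{xlbl}<->{glbl}",
                    )
                )
        if best_per_oxygen and candidates:
            candidates = [min(candidates, key=lambda b: b.distance)]
        bonds.extend(candidates)
    return bonds


def hbond_mode_tally(bonds: list[HBond]) -> Counter:
    """Counts of hydrogen bonds per donor/acceptor oxygen-identity mode."""
    return Counter(b.mode for b in bonds)
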