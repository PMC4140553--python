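"""Ideal helical glycan ribbons and glycosidic-torsion analysis.

For β-(1,4)-linked glycans the sum of the glycosidic dihedrals Φ + Ψ at
every linkage diagnoses the backbone screw symmetry: Φ + Ψ ≈ 120° gives a
twofold (2₁) helical screw — the flat ribbon that can lie along a cellulose
chain — while Φ + Ψ ≈ 50° (right-handed) or 190° (left-handed) gives a
threefold (3₁) screw, the solution conformation.

Torsion convention (one glycosidic convention, used consistently
throughout; the analysis depends only on the builder/measurer round trip):

    Φ = O5′–C1′–O4–C4      Ψ = C1′–O4–C4–C5

where primed atoms belong to the residue on the non-reducing side of the
linkage and O4/C4/C5 to the residue toward the reducing end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .chain import ResidueState, XylanChain
from .geometry import (
    RigidTransform,
    dihedral,
    fit_screw,
    kabsch,
    place_atom,
    screw_transform,
)
from .residues3d import Atom, RING_NAMES, decorated_template, xylose_template

__all__ = [
    "Fold",
    "FOLD_TARGET_SUM",
    "HelixSpec",
    "Conformation",
    "LinkageRecord",
    "build_ideal_helix",
    "compute_dihedrals",
    "classify_linkage",
    "screw_symmetry_rmsd",
    "align_to_z",
]

Fold = Literal["twofold", "threefold_right", "threefold_left"]

#: target Φ+Ψ (degrees) for each helical screw
FOLD_TARGET_SUM: dict[str, float] = {
    "twofold": 120.0,
    "threefold_right": 50.0,
    "threefold_left": 190.0,
}

#: signed screw-rotation angle per residue, as (value mod 360)
_FOLD_TARGET_ANGLE = {
    "twofold": 180.0,
    "threefold_right": 120.0,
    "threefold_left": 240.0,
}

GLYCOSIDIC_ANGLE = 117.0  # C1′–O4–C4 angle at the glycosidic oxygen


@dataclass(frozen=True)
class HelixSpec:
    """Recipe for an ideal helical ribbon.

    ``decoration`` supplies per-residue substituents (defaults to an
    undecorated chain of length ``dp``).  Only the sum Φ+Ψ is constrained by
    the conformational rule; the split (overridable with ``phi``) defaults
    to the balanced split on the *extended* branch, Φ = Ψ = sum/2 + 180°
    mod 360.  With rigid identical templates the screw-rotation angle
    depends on the sum alone, but the split selects the conformer along the
    constant-sum line: the extended branch maximizes the rise (~5.2 Å per
    residue, the fiber-repeat regime of β-(1,4) glycans) and lays the rings
    flat in the ribbon, whereas the compact branch (Φ = Ψ = sum/2) is a
    short-rise coil no real glycan adopts.
    """

    fold: Fold
    dp: int
    decoration: Optional[XylanChain] = None
    kind: str = "xylose"
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if self.decoration is not None and self.decoration.dp != self.dp:
            raise ValueError(
                f"decoration chain has dp={self.decoration.dp}, helix dp={self.dp}"
            )

    @property
    def target_sum(self) -> float:
        return FOLD_TARGET_SUM[self.fold]


@dataclass
class Conformation:
    """An all-heavy-atom 3D model of one glycan chain."""

    atoms: list[Atom]
    linkages: list[tuple[int, int]]  # (reducing-side residue i, residue i+1)
    chain_id: str = "X"
    kind: str = "xylose"

    @property
    def dp(self) -> int:
        return max(a.residue_index for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def atom(self, residue_index: int, name: str) -> Atom:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        raise KeyError(f"atom {name} of residue {residue_index} not found")

    def residue_coords(self, residue_index: int, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom(residue_index, n).xyz for n in names])

    def transformed(self, tr: RigidTransform) -> "Conformation":
        new = [
            Atom(a.name, a.element, a.residue_index, tr.apply(a.xyz[None, :])[0])
            for a in self.atoms
        ]
        return Conformation(new, list(self.linkages), self.chain_id, self.kind)

    def translated(self, shift: np.ndarray) -> "Conformation":
        shift = np.asarray(shift, float)
        new = [
            Atom(a.name, a.element, a.residue_index, a.xyz + shift)
            for a in self.atoms
        ]
        return Conformation(new, list(self.linkages), self.chain_id, self.kind)

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new = [
            Atom(a.name, a.element, a.residue_index, np.asarray(c, float))
            for a, c in zip(self.atoms, coords)
        ]
        return Conformation(new, list(self.linkages), self.chain_id, self.kind)


@dataclass(frozen=True)
class LinkageRecord:
    """Measured torsions of one glycosidic linkage."""

    linkage: int  # bond index: between residue `linkage` and `linkage + 1`
    phi: float
    psi: float
    sum: float  # (phi + psi) mod 360, in [0, 360)
    screw_class: str


def _template_linkage_params(kind: str) -> tuple[float, float, float]:
    """(d(C1–O1), d(O5–C1), angle O5–C1–O1) of the rigid template."""
    t = xylose_template()
    d_c1_o1 = float(np.linalg.norm(t["C1"] - t["O1"]))
    d_o5_c1 = float(np.linalg.norm(t["O5"] - t["C1"]))
    v1 = t["O5"] - t["C1"]
    v2 = t["O1"] - t["C1"]
    ang = float(
        np.degrees(
            np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
    )
    return d_c1_o1, d_o5_c1, ang


def _build(dp: int, phis: Sequence[float], psis: Sequence[float],
           decoration: Optional[XylanChain], kind: str, chain_id: str = "X") -> Conformation:
    """Chain rigid templates with the given per-linkage torsions."""
    if decoration is None:
        decoration = XylanChain(tuple(ResidueState(i) for i in range(1, dp + 1)))
    d_c1_o1, d_o5_c1, ang_o5_c1_o1 = _template_linkage_params(kind)
    template = {  # undecorated reference used for the 3-point fit
        name: pos for name, pos in xylose_template().items()
    }
    fit_names = ("C1", "O5", "O1")
    fit_src = np.array([template[n] for n in fit_names])

    atoms: list[Atom] = []
    prev: dict[str, np.ndarray] = {}
    for i in range(1, dp + 1):
        tpl = decorated_template(
            decoration.residue(i), kind=kind, keep_o1=(i == 1)
        )
        if i == 1:
            placed = {name: pos for name, elem, pos in tpl}
            for name, elem, pos in tpl:
                atoms.append(Atom(name, elem, i, pos.copy()))
        else:
            phi, psi = phis[i - 2], psis[i - 2]
            c1 = place_atom(
                prev["C5"], prev["C4"], prev["O4"],
                bond=d_c1_o1, angle=GLYCOSIDIC_ANGLE, torsion=psi,
            )
            o5 = place_atom(
                prev["C4"], prev["O4"], c1,
                bond=d_o5_c1, angle=ang_o5_c1_o1, torsion=phi,
            )
            tr, _ = kabsch(fit_src, np.array([c1, o5, prev["O4"]]))
            placed = {}
            for name, elem, pos in tpl:
                xyz = tr.apply(pos[None, :])[0]
                placed[name] = xyz
                atoms.append(Atom(name, elem, i, xyz))
        prev = placed
    linkages = [(i, i + 1) for i in range(1, dp)]
    return Conformation(atoms=atoms, linkages=linkages, chain_id=chain_id, kind=kind)


def build_ideal_helix(spec: HelixSpec) -> Conformation:
    """Build a rigid-template ribbon with Φ+Ψ equal to the fold's target sum.

    Every linkage gets the same (Φ, Ψ).  DP1 yields a single ring with zero
    linkages.
    """
    phi = (
        spec.phi
        if spec.phi is not None
        else (spec.target_sum / 2.0 + 180.0) % 360.0
    )
    psi = spec.target_sum - phi
    n_link = max(spec.dp - 1, 0)
    return _build(spec.dp, [phi] * n_link, [psi] * n_link, spec.decoration, spec.kind)


def compute_dihedrals(conf: Conformation, tol: float = 30.0) -> list[LinkageRecord]:
    """Recompute Φ, Ψ and their sum from Cartesian coordinates.

    Values are invariant under any rigid motion of the conformation.
    Raises ``KeyError`` naming the linkage and atom if a required atom is
    missing.
    """
    records = []
    for (i, j) in conf.linkages:
        try:
            o5p = conf.atom(j, "O5").xyz
            c1p = conf.atom(j, "C1").xyz
            o4 = conf.atom(i, "O4").xyz
            c4 = conf.atom(i, "C4").xyz
            c5 = conf.atom(i, "C5").xyz
        except KeyError as exc:
            raise KeyError(f"linkage {i}-{j}: {exc.args[0]}") from exc
        phi = dihedral(o5p, c1p, o4, c4)
        psi = dihedral(c1p, o4, c4, c5)
        s = (phi + psi) % 360.0
        records.append(
            LinkageRecord(
                linkage=i, phi=phi, psi=psi, sum=s,
                screw_class=classify_linkage(s, tol),
            )
        )
    return records


def classify_linkage(sum_deg: float, tol: float = 30.0) -> str:
    """Screw class of one linkage from its Φ+Ψ sum.

    Inclusive windows of half-width ``tol`` around 120° (twofold), 50°
    (threefold, right-handed) and 190° (threefold, left-handed); anything
    else is ``other``.  ``tol`` must stay below 35° so windows cannot
    overlap (the closest centers, 50 and 120, are 70° apart).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if tol >= 35.0:
        raise ValueError("tol must be < 35 degrees; windows would overlap")
    s = sum_deg % 360.0

    def dist(center: float) -> float:
        d = abs(s - center) % 360.0
        return min(d, 360.0 - d)

    if dist(120.0) <= tol:
        return "twofold"
    if dist(50.0) <= tol:
        return "threefold_right"
    if dist(190.0) <= tol:
        return "threefold_left"
    return "other"


def screw_symmetry_rmsd(conf: Conformation, fold: Fold) -> float:
    """RMSD of the chain from an exact n-fold screw.

    The screw axis, rise and axis point are taken from the unconstrained
    best-fit residue i -> i+1 transform; the rotation angle is then forced
    to the fold's 360/n° and the mapped residues compared with their
    successors.  A true n-fold helix scores ~0; evaluating a threefold
    helix as twofold (or vice versa) scores several Å.
    """
    if conf.dp < 3:
        raise ValueError("need dp >= 3 to assess screw symmetry")
    src = np.vstack(
        [conf.residue_coords(i, RING_NAMES) for i in range(1, conf.dp)]
    )
    tgt = np.vstack(
        [conf.residue_coords(i, RING_NAMES) for i in range(2, conf.dp + 1)]
    )
    sf = fit_screw(src, tgt)
    target = _FOLD_TARGET_ANGLE[fold]
    s = screw_transform(sf.axis, target, sf.rise, sf.point)
    mapped = s.apply(src)
    return float(np.sqrt(np.mean(np.sum((mapped - tgt) ** 2, axis=1))))


def align_to_z(conf: Conformation) -> Conformation:
    """Rigidly move the chain so its screw axis is +z through the origin,
    with the reducing end at low z."""
    if conf.dp < 2:
        return conf
    src = np.vstack(
        [conf.residue_coords(i, RING_NAMES) for i in range(1, conf.dp)]
    )
    tgt = np.vstack(
        [conf.residue_coords(i, RING_NAMES) for i in range(2, conf.dp + 1)]
    )
    sf = fit_screw(src, tgt)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(sf.axis, z)
    c = float(np.dot(sf.axis, z))
    if np.linalg.norm(v) < 1e-12:
        r = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        k = np.array(
            [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
        )
        r = np.eye(3) + k + k @ k / (1.0 + c)
    tr = RigidTransform(rotation=r, translation=-r @ sf.point)
    out = conf.transformed(tr)
    # center the chain along z and keep x/y centered on the axis
    coords = out.coords()
    shift = np.array([0.0, 0.0, -float(coords[:, 2].mean())])
    return out.translated(shift)
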