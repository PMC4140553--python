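"""Simplified cellulose Iβ face lattices and xylan-ribbon docking.

A crystalline cellulose Iβ microfibril presents hydrophilic faces —
(010)/(020), exposing the hydroxyl-rich ribbon edges — and hydrophobic
faces, (100)/(200), exposing the CH ring faces.  Here each face is reduced
to the features the steric argument needs: twofold glucan ribbons running
along z, laid flat in sheets (ribbon plane = sheet plane), with the sheet
stacked below at the inter-sheet distance.  On a hydrophilic face the xylan
ribbon docks into a chain *vacancy* — a missing-chain groove flanked by
glucan neighbors — whereas on a hydrophobic face it simply stacks on top of
the intact surface plane.

Lattice defaults follow published Iβ geometry in spirit (intra-sheet chain
spacing ~8.2 Å, inter-sheet spacing ~3.9 Å) and are fully configurable:
this is a steric/H-bond model, not a crystal structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import RigidTransform
from .helix import Conformation, HelixSpec, align_to_z, build_ideal_helix
from .residues3d import RING_NAMES

__all__ = [
    "FACE_POLARITY",
    "CelluloseFace",
    "LatticeParams",
    "PosedSystem",
    "orient_ribbon",
    "build_face_and_dock",
]

FACE_POLARITY = {
    "010": "hydrophilic",
    "020": "hydrophilic",
    "110": "hydrophilic",
    "1-10": "hydrophilic",
    "100": "hydrophobic",
    "200": "hydrophobic",
}


@dataclass(frozen=True)
class LatticeParams:
    """Simplified face-lattice geometry (Å)."""

    chain_spacing: float = 8.2   # between chain axes within a sheet (x)
    sheet_spacing: float = 3.9   # between sheets (y)
    sheet_stagger: float = 0.0   # x offset of the second sheet
    stack_height: float = 6.5    # ribbon-on-plane distance, hydrophobic faces
    dock_lift: float = 0.4       # +y offset of a docked xylan ribbon
    dock_z_shift: float = 0.0    # axial registration of the docked ribbon


@dataclass(frozen=True)
class CelluloseFace:
    face_id: str
    polarity: str
    chain_positions: tuple[tuple[float, float], ...]  # (x, y) chain axes
    vacancy_index: Optional[int]
    lattice: LatticeParams

    def __post_init__(self) -> None:
        if self.face_id not in FACE_POLARITY:
            raise ValueError(
                f"unknown face id {self.face_id!r}; have {sorted(FACE_POLARITY)}"
            )


@dataclass
class PosedSystem:
    """A xylan ribbon posed against a cellulose face."""

    xylan: Conformation
    cellulose: list[Conformation]
    face: CelluloseFace

    def translated_xylan(self, shift: np.ndarray) -> "PosedSystem":
        return PosedSystem(
            xylan=self.xylan.translated(shift),
            cellulose=self.cellulose,
            face=self.face,
        )


_SUBSTITUENT_PREFIXES = ("C2A", "O2A", "C2M", "C3A", "O3A", "C3M", "GA")


def _is_substituent(name: str) -> bool:
    return any(name.startswith(p) for p in _SUBSTITUENT_PREFIXES)


def _rotate_z(conf: Conformation, angle_deg: float) -> Conformation:
    th = np.radians(angle_deg)
    r = np.array(
        [
            [np.cos(th), -np.sin(th), 0.0],
            [np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return conf.transformed(RigidTransform(rotation=r, translation=np.zeros(3)))


def orient_ribbon(conf: Conformation, decorated_toward: str = "+y") -> Conformation:
    """Align a ribbon's axis to z and lay it flat.

    The ribbon is rotated about its axis so the widest in-plane direction of
    its *ring* atoms lies along x — the flat orientation of a chain within a
    cellulose sheet.  If substituents are present the flat ribbon is then
    flipped (180° about z) if needed so their mean direction points toward
    ``decorated_toward`` (+y = away from a crystal below); for an
    alternate-decorated ribbon this puts every substituent on the solvent
    side, while mixed-parity patterns necessarily keep some on each face.
    """
    conf = align_to_z(conf)
    ring_xy = np.array(
        [a.xyz[:2] for a in conf.atoms if a.name in RING_NAMES]
    )
    c = ring_xy - ring_xy.mean(axis=0)
    vals, vecs = np.linalg.eigh(c.T @ c)
    main = vecs[:, np.argmax(vals)]
    ang = np.degrees(np.arctan2(main[1], main[0]))
    conf = _rotate_z(conf, -ang)
    sub_y = np.array(
        [a.xyz[1] for a in conf.atoms if _is_substituent(a.name)]
    )
    if sub_y.size:
        want_up = decorated_toward == "+y"
        if (sub_y.mean() > 0) != want_up:
            conf = _rotate_z(conf, 180.0)
    return conf


def _glucan_chain(dp: int, chain_id: str) -> Conformation:
    conf = build_ideal_helix(HelixSpec(fold="twofold", dp=dp, kind="glucose"))
    conf = orient_ribbon(conf)
    conf.chain_id = chain_id
    return conf


def build_face_and_dock(
    face_id: str,
    n_chains: int,
    vacancy: Optional[int],
    ribbon: Conformation,
    lattice: LatticeParams = LatticeParams(),
    cellulose_dp: Optional[int] = None,
) -> PosedSystem:
    """Pose ``ribbon`` against a simplified cellulose face.

    Hydrophilic faces: ``n_chains`` glucan chains form the surface sheet
    with chain ``vacancy`` absent; a second sheet lies one inter-sheet
    spacing below (directly below by default, offset by ``sheet_stagger``);
    the ribbon (decorations oriented to the solvent, +y) occupies the
    vacancy groove with its axis parallel to the cellulose chains.
    Hydrophobic faces: one intact sheet, ribbon stacked on top (no groove,
    decorations on either side are tolerated).
    """
    polarity = FACE_POLARITY.get(face_id)
    if polarity is None:
        raise ValueError(f"unknown face id {face_id!r}; have {sorted(FACE_POLARITY)}")
    dp = cellulose_dp if cellulose_dp is not None else ribbon.dp
    base = _glucan_chain(dp, "C")

    chains: list[Conformation] = []
    positions: list[tuple[float, float]] = []
    if polarity == "hydrophilic":
        if vacancy is None:
            vacancy = n_chains // 2
        if not 0 <= vacancy < n_chains:
            raise ValueError(f"vacancy index {vacancy} outside 0..{n_chains - 1}")
        for k in range(n_chains):
            x = (k - vacancy) * lattice.chain_spacing
            positions.append((x, 0.0))
            if k == vacancy:
                continue
            chains.append(base.translated(np.array([x, 0.0, 0.0])))
        # second sheet below (directly below the surface chains by default)
        for k in range(n_chains):
            x = (k - vacancy) * lattice.chain_spacing + lattice.sheet_stagger
            positions.append((x, -lattice.sheet_spacing))
            chains.append(
                base.translated(np.array([x, -lattice.sheet_spacing, 0.0]))
            )
        xylan = orient_ribbon(ribbon, decorated_toward="+y").translated(
            np.array([0.0, lattice.dock_lift, lattice.dock_z_shift])
        )
    else:
        vacancy = None
        for k in range(n_chains):
            x = (k - n_chains // 2) * lattice.chain_spacing
            positions.append((x, 0.0))
            chains.append(base.translated(np.array([x, 0.0, 0.0])))
        xylan = orient_ribbon(ribbon, decorated_toward="+y").translated(
            np.array([0.0, lattice.stack_height, 0.0])
        )

    face = CelluloseFace(
        face_id=face_id,
        polarity=polarity,
        chain_positions=tuple(positions),
        vacancy_index=vacancy,
        lattice=lattice,
    )
    for i, ch in enumerate(chains):
        ch.chain_id = f"C{i}"
    return PosedSystem(xylan=xylan, cellulose=chains, face=face)
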