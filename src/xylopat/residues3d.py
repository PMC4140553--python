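"""Idealized pyranose templates and substituent attachment.

A rigid 4C1 chair template is used for every sugar: six ring atoms
(O5, C1..C5) on an ideal chair (ring bond ~1.53 Å), with exocyclic oxygens
placed equatorially — the all-equatorial arrangement of β-D-xylopyranose
(and of the glucopyranosyl units of cellulose, which additionally carry the
C6/O6 hydroxymethyl at C5).  O1 marks the anomeric (β) bond direction; when
a residue is glycosylated its O1 is replaced by the O4 of the next residue
toward the reducing end.

Decorations are attached in the template frame before the residue is posed:
acetyl esters as a three-atom (C=O, CH3) group on O2/O3, and a GlcA side
chain as a simplified six-atom ring marker on O2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import Glca, ResidueState
from .geometry import _unit

__all__ = ["Atom", "xylose_template", "glucose_template", "decorated_template"]

RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")

# idealized internal geometry (Å / degrees)
RING_RADIUS = 1.45
RING_PUCKER = 0.25
C_O_BOND = 1.43
ESTER_C_O = 1.36
CARBONYL = 1.22
C_C_BOND = 1.51
SUBST_HALF_ANGLE = 54.75  # half the tetrahedral angle, for eq/ax directions
ESTER_ANGLE = 117.0  # C(ring)–O–C(ester) angle at the substituted oxygen


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB-style name, element, residue and position."""

    name: str
    element: str
    residue_index: int
    xyz: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


def _ring_coords(mirror: bool = False) -> dict[str, np.ndarray]:
    """Ideal chair: alternating ring atoms above/below the mean plane."""
    coords = {}
    for k, name in enumerate(RING_NAMES):
        ang = np.radians(60.0 * k)
        z = RING_PUCKER * (1 if k % 2 == 0 else -1)
        coords[name] = np.array(
            [RING_RADIUS * np.cos(ang), RING_RADIUS * np.sin(ang), z]
        )
    if mirror:
        for name in coords:
            coords[name] = coords[name] * np.array([1.0, -1.0, 1.0])
    return coords


def _substituent_dirs(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(equatorial, axial) unit directions at ring atom ``x`` with ring
    neighbors ``a`` and ``b``."""
    u = _unit(-(_unit(a - x) + _unit(b - x)))
    n = _unit(np.cross(a - x, b - x))
    beta = np.radians(SUBST_HALF_ANGLE)
    d1 = _unit(u * np.cos(beta) + n * np.sin(beta))
    d2 = _unit(u * np.cos(beta) - n * np.sin(beta))
    # the axial direction is the one more parallel to the ring axis (z)
    if abs(d1[2]) > abs(d2[2]):
        return d2, d1
    return d1, d2


def _neighbors(name: str) -> tuple[str, str]:
    i = RING_NAMES.index(name)
    return RING_NAMES[(i - 1) % 6], RING_NAMES[(i + 1) % 6]


def xylose_template(mirror: bool = True) -> dict[str, np.ndarray]:
    """β-D-xylopyranose template: ring + equatorial O1, O2, O3, O4.

    ``mirror`` selects the enantiomer whose threefold screw handedness
    matches the β-D series (Φ+Ψ = 50° right-handed, 190° left-handed).
    """
    t = _ring_coords(mirror=mirror)
    for carbon, oxy in (("C1", "O1"), ("C2", "O2"), ("C3", "O3"), ("C4", "O4")):
        a, b = _neighbors(carbon)
        eq, _ax = _substituent_dirs(t[carbon], t[a], t[b])
        t[oxy] = t[carbon] + C_O_BOND * eq
    return t


def glucose_template(mirror: bool = True) -> dict[str, np.ndarray]:
    """β-D-glucopyranose template: xylose plus the C6/O6 hydroxymethyl."""
    t = xylose_template(mirror=mirror)
    a, b = _neighbors("C5")
    eq, ax = _substituent_dirs(t["C5"], t[a], t[b])
    t["C6"] = t["C5"] + C_C_BOND * eq
    # O6 extends outward, tilted toward the axial side so it protrudes
    # from the ring plane and is available for interchain hydrogen bonds
    t["O6"] = t["C6"] + C_O_BOND * _unit(eq + 0.8 * ax)
    return t


def _group_direction(o_pos: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    """Outward direction of a substituent group attached at an O2/O3 oxygen.

    The bond from the substituted oxygen to the group carbon makes the
    ester C–O–C angle (~117°) with the ring C–O bond; its azimuth about
    that bond is free.  The rotamer modelled here points the group along
    the ring normal (template +z), the orientation of the substituents of a
    flat twofold ribbon standing perpendicular to the ribbon face — so all
    substituents of same-parity residues of a 2₁ ribbon sit on the same
    face.
    """
    eq = _unit(o_pos - c_pos)
    n = np.array([0.0, 0.0, 1.0])
    n_perp = _unit(n - np.dot(n, eq) * eq)
    th = np.radians(180.0 - ESTER_ANGLE)
    return _unit(np.cos(th) * eq + np.sin(th) * n_perp)


def _acetyl_atoms(o_pos: np.ndarray, c_pos: np.ndarray, tag: str) -> list[tuple[str, str, np.ndarray]]:
    """Ester acetyl group extending outward from hydroxyl oxygen ``o_pos``.

    sp2 carbonyl carbon: the methyl carbon and carbonyl oxygen sit at
    ±60° from the O→C direction (the trans-ester zigzag), so the group
    extends away from the ring rather than folding back over it.
    """
    out = _group_direction(o_pos, c_pos)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(out, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = _unit(np.cross(out, ref))
    cc = o_pos + ESTER_C_O * out
    co = cc + CARBONYL * _unit(out * np.cos(np.radians(60)) + perp * np.sin(np.radians(60)))
    cm = cc + C_C_BOND * _unit(out * np.cos(np.radians(-60)) - perp * np.sin(np.radians(60)))
    return [
        (f"C{tag}A", "C", cc),
        (f"O{tag}A", "O", co),
        (f"C{tag}M", "C", cm),
    ]


def _glca_atoms(o_pos: np.ndarray, c_pos: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Simplified GlcA side chain: a six-atom ring marker on O2.

    The marker ring stands edge-on, extending away from the backbone along
    the substituent direction (its plane contains that direction), the
    compact pose of a glycosidically linked side sugar.
    """
    out = _group_direction(o_pos, c_pos)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(out, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(out, ref))
    center = o_pos + (ESTER_C_O + RING_RADIUS) * out
    atoms = []
    for k in range(6):
        ang = np.radians(60.0 * k)
        pos = center + RING_RADIUS * (np.cos(ang) * out + np.sin(ang) * u)
        elem = "O" if k == 0 else "C"
        atoms.append((f"GA{k + 1}", elem, pos))
    return atoms


def decorated_template(
    state: ResidueState,
    kind: str = "xylose",
    keep_o1: bool = False,
    mirror: bool = True,
) -> list[tuple[str, str, np.ndarray]]:
    """Template atom list (name, element, xyz) for one decorated residue.

    ``keep_o1`` retains the anomeric oxygen (reducing-end residue only);
    interior residues lose O1 because the glycosidic oxygen belongs to the
    next residue's O4.
    """
    t = glucose_template(mirror) if kind == "glucose" else xylose_template(mirror)
    atoms: list[tuple[str, str, np.ndarray]] = []
    for name, pos in t.items():
        if name == "O1" and not keep_o1:
            continue
        atoms.append((name, name[0], pos))
    if state.ac2:
        atoms.extend(_acetyl_atoms(t["O2"], t["C2"], tag="2"))
    if state.ac3:
        atoms.extend(_acetyl_atoms(t["O3"], t["C3"], tag="3"))
    if state.glca is not Glca.NONE:
        atoms.extend(_glca_atoms(t["O2"], t["C2"]))
    return atoms
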