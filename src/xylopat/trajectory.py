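"""Gaussian-jitter frame ensembles and the analyses run on them.

A stand-in for thermal motion: frames are independent copies of a built
conformation with i.i.d. Gaussian noise (sd ``jitter_sd`` Å) on every
coordinate.  This produces the unimodal torsion scatter needed to exercise
the Φ+Ψ histogram and interchain-separation analyses; it does *not* model
correlated backbone motion, solvent, or barrier crossings between screw
states.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cellulose import PosedSystem
from .helix import Conformation, compute_dihedrals

__all__ = [
    "synthetic_trajectory",
    "phi_psi_sums",
    "phi_psi_histogram",
    "interchain_separation",
]

BACKBONE_OXYGENS = ("O4", "O5")


def synthetic_trajectory(
    conf: Conformation, jitter_sd: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """(n_frames, n_atoms, 3) array of independently jittered copies."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = conf.coords()
    noise = rng.normal(0.0, jitter_sd, size=(n_frames, *base.shape)) if jitter_sd > 0 \
        else np.zeros((n_frames, *base.shape))
    return base[None, :, :] + noise


def phi_psi_sums(conf: Conformation, frames: np.ndarray) -> np.ndarray:
    """(n_frames, n_linkages) matrix of per-linkage Φ+Ψ sums (degrees)."""
    sums = []
    for frame in frames:
        c = conf.with_coords(frame)
        sums.append([rec.sum for rec in compute_dihedrals(c)])
    return np.array(sums)


def phi_psi_histogram(
    conf: Conformation, frames: np.ndarray, bins: int = 36
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-linkage Φ+Ψ over all frames, on [0°, 360°)."""
    sums = phi_psi_sums(conf, frames).ravel()
    return np.histogram(sums, bins=bins, range=(0.0, 360.0))


def _backbone_oxygens(conf: Conformation) -> dict[int, np.ndarray]:
    out: dict[int, list[np.ndarray]] = {}
    for a in conf.atoms:
        if a.name in BACKBONE_OXYGENS:
            out.setdefault(a.residue_index, []).append(a.xyz)
    return {k: np.array(v) for k, v in out.items()}


def interchain_separation(
    posed: PosedSystem, xylan_frames: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-residue xylan–glucan interchain separation d_O–O (Å).

    For each xylan residue, the minimum distance between its backbone
    oxygens (O4/O5) and any cellulose backbone oxygen; cellulose is held
    fixed.  Returns (n_frames, dp); with no frames, a single row measured
    on the posed coordinates.
    """
    cell_ox = np.vstack(
        [ox for ch in posed.cellulose for ox in _backbone_oxygens(ch).values()]
    )
    conf = posed.xylan
    idx_by_res: dict[int, list[int]] = {}
    for i, a in enumerate(conf.atoms):
        if a.name in BACKBONE_OXYGENS:
            idx_by_res.setdefault(a.residue_index, []).append(i)
    frames = (
        xylan_frames if xylan_frames is not None else conf.coords()[None, :, :]
    )
    dp = conf.dp
    out = np.empty((frames.shape[0], dp))
    for f, frame in enumerate(frames):
        for r in range(1, dp + 1):
            pts = frame[idx_by_res[r]]
            d = np.linalg.norm(pts[:, None, :] - cell_ox[None, :, :], axis=2)
            out[f, r - 1] = float(d.min())
    return out
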