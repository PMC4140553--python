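"""Steric and hydrogen-bond consequences of decoration patterning.

Docks twofold xylan ribbons into a chain vacancy on the hydrophilic (010)
cellulose face: with acetyls on alternate residues every substituent points
to the solvent and the pose is clash-free; with odd-spaced acetyls (both
ribbon faces decorated) the buried acetyl collides with the crystal.  On
the hydrophobic (100) face both patterns stack without clashes.  The
dominant xylan–cellulose hydrogen-bond mode on the docked pose is
xylosyl O2 <-> glucosyl O6.
"""

import numpy as np

from xylopat.cellulose import build_face_and_dock
from xylopat.chain import ResidueState, XylanChain
from xylopat.contacts import clash_score, detect_hbonds, hbond_mode_tally
from xylopat.helix import HelixSpec, build_ideal_helix
from xylopat.trajectory import interchain_separation


def decorated(positions):
    return XylanChain(
        tuple(ResidueState(i, ac3=(i in set(positions))) for i in range(1, 11))
    )


even = build_ideal_helix(HelixSpec(fold="twofold", dp=10, decoration=decorated(range(2, 11, 2))))
odd = build_ideal_helix(HelixSpec(fold="twofold", dp=10, decoration=decorated([2, 5, 8])))

for name, rib, face in (("even/010", even, "010"), ("odd/010", odd, "010"),
                        ("even/100", even, "100"), ("odd/100", odd, "100")):
    posed = build_face_and_dock(face, n_chains=5, vacancy=2 if face == "010" else None, ribbon=rib)
    rep = clash_score(posed)
    print(f"{name:9s} clashes={rep.n_clashes}  min separation={rep.min_separation:.2f} Å")

posed = build_face_and_dock("010", 5, 2, even)
tally = hbond_mode_tally(detect_hbonds(posed))
print("H-bond modes on the even/010 pose:", dict(tally.most_common(3)))
d_docked = interchain_separation(posed).mean()
d_desorbed = interchain_separation(posed.translated_xylan(np.array([0, 5.0, 0]))).mean()
print(f"mean interchain d_O–O: docked {d_docked:.2f} Å vs desorbed {d_desorbed:.2f} Å")
print("-> only the alternate pattern fits the hydrophilic groove; O2->O6 dominates.")
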