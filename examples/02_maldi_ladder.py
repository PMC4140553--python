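"""Predict the MALDI ladder of a partial xylanase digest.

Partially digests strictly alternating 3-O-acetylated xylan and prints the
dominant predicted [M+Na]+ peaks of the 2-AA-labelled products.  The ladder
is dominated by even-DP species carrying DP/2 acetyl groups — Xyl4Ac2 at
nominal m/z 774, Xyl6Ac3 at 1080, Xyl8Ac4 at 1386.
"""

import numpy as np

from xylopat import CM_XYN10B, digest, nominal_mz, spectrum_from_products
from xylopat.chain import ResidueState, XylanChain

chain = XylanChain(
    tuple(ResidueState(i, ac3=(i % 2 == 0)) for i in range(1, 51))
)
products = []
for k in range(200):
    rng = np.random.default_rng([2, k])
    products.extend(
        digest(chain, CM_XYN10B, mode="partial", site_prob=0.5, rng=rng).products
    )

entries = spectrum_from_products(products, label="2AA", adduct="M+Na")
print("m/z (nominal)  abundance  composition")
for e in sorted(entries, key=lambda e: -e.relative_abundance)[:8]:
    print(f"{nominal_mz(e.mz):>12d}  {e.relative_abundance:>9.3f}  {e.composition}")
print("-> every second residue acetylated: DP4/DP6/DP8 products carry 2/3/4 acetyls.")
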