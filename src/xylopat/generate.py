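"""Synthetic decorated-xylan generator.

Emulates the decoration hypotheses under study for dicot glucuronoxylan:

* ``alternating`` — acetyl groups on strictly alternate xylosyl residues
  (the pattern inferred for Arabidopsis secondary-wall xylan);
* ``bernoulli`` — i.i.d. random acetylation, the null hypothesis;
* ``composition`` — residue types drawn i.i.d. from given (X, X2, X3, X23)
  fractions, e.g. NMR-integration compositions.

GlcA side chains can be added evenly spaced (major-domain hypothesis) or at
random (minor domain), and non-enzymatic O2<->O3 acetyl migration can be
applied.  All randomness flows through numpy Generators; a single ensemble
seed spawns one independent stream per chain so ensembles are
order-independent and exactly reproducible.
"""

from __future__ import annotations

import logging
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .chain import Glca, ResidueState, XylanChain

__all__ = [
    "SubstitutionSpec",
    "generate_chain",
    "generate_ensemble",
    "add_glca",
    "apply_migration",
]

logger = logging.getLogger(__name__)

_PROB_SUM_TOL = 1e-9


class SubstitutionSpec(BaseModel, extra="forbid"):
    """Parameters of one decoration hypothesis.

    ``o2_fraction``, ``o3_fraction`` and ``di_fraction`` partition each
    acetylation event between 2-O, 3-O and 2,3-di-O placement (they must sum
    to 1).  The defaults loosely echo the measured mono/di acetylation
    ratios of Arabidopsis xylan.  ``composition`` is the i.i.d. residue-type
    law (p_X, p_X2, p_X3, p_X23) used by ``composition`` mode.
    """

    mode: Literal["alternating", "bernoulli", "composition"] = "alternating"
    dp: int = Field(default=50, ge=1)
    p_ac: float = Field(default=0.5, ge=0.0, le=1.0)
    phase: Literal["odd", "even"] = "even"
    o2_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    o3_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    di_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    composition: tuple[float, float, float, float] = (0.556, 0.153, 0.266, 0.025)
    glca_mode: Literal["none", "even_spaced", "random"] = "none"
    glca_spacing: int = Field(default=6, ge=2)
    glca_p: float = Field(default=0.1, ge=0.0, le=1.0)
    migration_p: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_partitions(self) -> "SubstitutionSpec":
        s = self.o2_fraction + self.o3_fraction + self.di_fraction
        if abs(s - 1.0) > _PROB_SUM_TOL:
            raise ValueError(
                f"o2_fraction + o3_fraction + di_fraction must sum to 1, got {s}"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.composition):
            raise ValueError("composition: every probability must lie in [0, 1]")
        c = sum(self.composition)
        if abs(c - 1.0) > _PROB_SUM_TOL:
            raise ValueError(f"composition must sum to 1, got {c}")
        return self


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _acetyl_flags(rng: np.random.Generator, spec: SubstitutionSpec) -> tuple[bool, bool]:
    """Draw (ac2, ac3) for one acetylation event."""
    u = rng.random()
    if u < spec.o2_fraction:
        return True, False
    if u < spec.o2_fraction + spec.o3_fraction:
        return False, True
    return True, True


def generate_chain(
    spec: SubstitutionSpec, rng: Optional[np.random.Generator] = None
) -> XylanChain:
    """Generate one backbone under ``spec`` (acetylation only).

    GlcA placement and acetyl migration are separate steps (`add_glca`,
    `apply_migration`); `generate_ensemble` composes all three.
    """
    rng = _rng(spec.seed if rng is None else rng)
    states: list[ResidueState] = []
    if spec.mode == "alternating":
        target_parity = 0 if spec.phase == "even" else 1
        for i in range(1, spec.dp + 1):
            if i % 2 == target_parity:
                ac2, ac3 = _acetyl_flags(rng, spec)
            else:
                ac2 = ac3 = False
            states.append(ResidueState(i, ac2=ac2, ac3=ac3))
    elif spec.mode == "bernoulli":
        for i in range(1, spec.dp + 1):
            if rng.random() < spec.p_ac:
                ac2, ac3 = _acetyl_flags(rng, spec)
            else:
                ac2 = ac3 = False
            states.append(ResidueState(i, ac2=ac2, ac3=ac3))
    else:  # composition
        kinds = rng.choice(4, size=spec.dp, p=list(spec.composition))
        flag = {0: (False, False), 1: (True, False), 2: (False, True), 3: (True, True)}
        states = [
            ResidueState(i + 1, ac2=flag[int(k)][0], ac3=flag[int(k)][1])
            for i, k in enumerate(kinds)
        ]
    return XylanChain(tuple(states))


def add_glca(
    chain: XylanChain,
    spec: SubstitutionSpec,
    rng: Optional[np.random.Generator] = None,
    kind: Glca = Glca.GLCA,
) -> XylanChain:
    """Place GlcA decorations on ``chain`` per ``spec.glca_mode``.

    ``even_spaced`` puts a GlcA every ``glca_spacing`` residues starting at
    a seeded random offset in 1..spacing; ``random`` places them i.i.d. with
    probability ``glca_p``.  A residue whose O2 already carries an acetyl is
    skipped (logged): O2 can hold only one substituent.
    """
    if spec.glca_mode == "none":
        raise ValueError("add_glca called with glca_mode='none'")
    rng = _rng(spec.seed if rng is None else rng)
    if spec.glca_mode == "even_spaced":
        if spec.glca_spacing < 2:
            raise ValueError("glca_spacing must be >= 2 in even_spaced mode")
        start = int(rng.integers(1, spec.glca_spacing + 1))
        targets = set(range(start, chain.dp + 1, spec.glca_spacing))
    else:  # random
        targets = {
            i for i in range(1, chain.dp + 1) if rng.random() < spec.glca_p
        }
    new = []
    for res in chain:
        if res.index in targets:
            if res.ac2:
                logger.info(
                    "skipping GlcA at position %d: O2 already acetylated", res.index
                )
                new.append(res)
            else:
                new.append(ResidueState(res.index, ac2=False, ac3=res.ac3, glca=kind))
        else:
            new.append(res)
    return XylanChain(tuple(new))


def apply_migration(
    chain: XylanChain,
    migration_p: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> XylanChain:
    """O2<->O3 acetyl migration on singly acetylated residues.

    Each X2 (X3) residue becomes X3 (X2) with probability ``migration_p``;
    X and X23 residues are untouched, so the total acetyl count is
    conserved.
    """
    if not 0.0 <= migration_p <= 1.0:
        raise ValueError(f"migration_p must lie in [0, 1], got {migration_p}")
    rng = _rng(seed if rng is None else rng)
    new = []
    for res in chain:
        if res.ac2 != res.ac3 and rng.random() < migration_p:
            if res.glca is not Glca.NONE and res.ac3:
                # migration onto O2 blocked by the GlcA already there
                new.append(res)
            else:
                new.append(
                    ResidueState(res.index, ac2=res.ac3, ac3=res.ac2, glca=res.glca)
                )
        else:
            new.append(res)
    return XylanChain(tuple(new))


def generate_ensemble(
    spec: SubstitutionSpec, n_chains: int, seed: Optional[int] = None
) -> list[XylanChain]:
    """Generate ``n_chains`` independent chains under ``spec``.

    Chain *k* uses the stream seeded by ``(seed, k)``, so the ensemble is
    reproducible and independent of generation order.  GlcA placement and
    migration are applied per ``spec``.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    base = spec.seed if seed is None else seed
    chains = []
    for k in range(n_chains):
        rng = np.random.default_rng([base, k])
        chain = generate_chain(spec, rng)
        if spec.glca_mode != "none":
            chain = add_glca(chain, spec, rng)
        if spec.migration_p > 0:
            chain = apply_migration(chain, spec.migration_p, rng)
        chains.append(chain)
    return chains
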