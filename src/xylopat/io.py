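"""Line-oriented and tabular readers/writers for chains, products and spectra.

Chain ensembles travel either as one chain string per line (see
`xylopat.chain`) or as a TSV with one row per residue (chain, position, ac2,
ac3, glca).  Digestion products and predicted spectra are TSV.  All readers
raise location-bearing errors on malformed input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .chain import ChainParseError, Glca, ResidueState, XylanChain, chain_from_string, chain_to_string
from .digest import DigestResult
from .masses import SpectrumEntry

__all__ = [
    "write_chain_strings",
    "read_chain_strings",
    "write_chains_tsv",
    "read_chains_tsv",
    "write_products_tsv",
    "read_products_tsv",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
]

PathLike = Union[str, Path]


def write_chain_strings(chains: Sequence[XylanChain], path: PathLike) -> None:
    Path(path).write_text(
        "".join(chain_to_string(c) + "\n" for c in chains), encoding="utf-8"
    )


def read_chain_strings(path: PathLike) -> list[XylanChain]:
    chains = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            chains.append(chain_from_string(line))
        except ChainParseError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not chains:
        raise ValueError(f"{path}: no chains found")
    return chains


def chains_to_frame(chains: Sequence[XylanChain]) -> pd.DataFrame:
    rows = [
        {
            "chain": ci,
            "position": r.index,
            "ac2": int(r.ac2),
            "ac3": int(r.ac3),
            "glca": r.glca.value,
        }
        for ci, c in enumerate(chains)
        for r in c
    ]
    return pd.DataFrame(rows)


def write_chains_tsv(chains: Sequence[XylanChain], path: PathLike) -> None:
    chains_to_frame(chains).to_csv(path, sep="\t", index=False)


def read_chains_tsv(path: PathLike) -> list[XylanChain]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    required = {"chain", "position", "ac2", "ac3", "glca"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    chains = []
    for cid, sub in df.groupby("chain", sort=True):
        sub = sub.sort_values("position")
        try:
            states = [
                ResidueState(
                    index=int(row.position),
                    ac2=bool(row.ac2),
                    ac3=bool(row.ac3),
                    glca=Glca(row.glca),
                )
                for row in sub.itertuples()
            ]
            chains.append(XylanChain(tuple(states)))
        except ValueError as exc:
            raise ValueError(f"{path}: chain {cid}: {exc}") from exc
    return chains


def write_products_tsv(
    results: Sequence[DigestResult], path: PathLike
) -> None:
    rows = []
    for ci, res in enumerate(results):
        for pi, p in enumerate(res.products):
            rows.append(
                {
                    "chain": ci,
                    "product": pi,
                    "enzyme": res.enzyme,
                    "dp": p.dp,
                    "n_ac": p.n_ac,
                    "n_glca": p.n_glca,
                    "parent_start": p.parent_start,
                    "parent_end": p.parent_end,
                    "chain_string": chain_to_string(p.to_chain()),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_products_tsv(path: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    required = {"chain", "product", "dp", "n_ac", "n_glca", "parent_start", "parent_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_spectrum_tsv(entries: Sequence[SpectrumEntry], path: PathLike) -> None:
    rows = [
        {
            "mz": round(e.mz, 4),
            "relative_abundance": e.relative_abundance,
            "composition": str(e.composition),
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    missing = {"mz", "relative_abundance", "composition"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
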