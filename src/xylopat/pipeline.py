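"""Config-driven orchestration: generate -> digest -> spectrum / NMR stats,
plus the structural workflow, with uniform seeding and a run manifest.

A run is described by one `RunConfig` (YAML on disk); stages execute in
dependency order, every output lands in the run directory, and the manifest
records the config hash and every file written.  The same config + seed
reproduces byte-identical outputs.  Each stage derives its random stream
from the global seed, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field

from .cellulose import LatticeParams, build_face_and_dock
from .chain import ResidueState, XylanChain
from .contacts import clash_score, detect_hbonds, hbond_mode_tally
from .digest import digest, get_enzyme, product_summary
from .generate import SubstitutionSpec, generate_ensemble
from .helix import HelixSpec, build_ideal_helix, compute_dihedrals
from .io import (
    read_chain_strings,
    read_chains_tsv,
    read_products_tsv,
    read_spectrum_tsv,
    write_chain_strings,
    write_chains_tsv,
    write_products_tsv,
    write_spectrum_tsv,
)
from .masses import spectrum_from_products
from .nmr import ensemble_report
from .pdbio import read_pdb, write_pdb, write_posed_pdb

__all__ = ["MsConfig", "StructureConfig", "RunConfig", "run_pipeline", "io_roundtrips"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "digest", "spectrum", "nmr_stats", "structure")
_DEPS = {"digest": "generate", "spectrum": "digest", "nmr_stats": "generate"}


class MsConfig(BaseModel, extra="forbid"):
    label: Literal["none", "2AA"] = "2AA"
    adduct: Literal["M+Na", "M+H"] = "M+Na"


class StructureConfig(BaseModel, extra="forbid"):
    fold: Literal["twofold", "threefold_right", "threefold_left"] = "twofold"
    dp: int = Field(default=10, ge=1)
    face: str = "010"
    n_cellulose_chains: int = Field(default=5, ge=1)
    vacancy: Optional[int] = None
    decorate: bool = True          # alternate 3-O-acetyl decoration on the ribbon
    hbond_d_max: float = 3.5
    clash_scale: float = 0.7
    lattice: dict = Field(default_factory=dict)  # LatticeParams overrides


class RunConfig(BaseModel, extra="forbid"):
    stages: list[Literal["generate", "digest", "spectrum", "nmr_stats", "structure"]]
    substitution: SubstitutionSpec = Field(default_factory=SubstitutionSpec)
    n_chains: int = Field(default=50, ge=1)
    enzyme: str = "CmXyn10B"
    digest_mode: Literal["complete", "partial"] = "complete"
    site_prob: Optional[float] = None
    ms: MsConfig = Field(default_factory=MsConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    seed: int = 0
    outdir: str = "run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _alternating_ac3(dp: int) -> XylanChain:
    return XylanChain(
        tuple(ResidueState(i, ac3=(i % 2 == 0)) for i in range(1, dp + 1))
    )


def run_pipeline(config: RunConfig, outdir: Optional[Union[str, Path]] = None) -> dict:
    """Execute the selected stages; return (and write) the run manifest."""
    for stage in config.stages:
        dep = _DEPS.get(stage)
        if dep is not None and dep not in config.stages:
            raise ValueError(
                f"stage {stage!r} requires upstream stage {dep!r}, which is "
                "not selected and no input file is configured"
            )
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    outputs: dict[str, str] = {}

    enzyme = get_enzyme(config.enzyme)
    logger.info("enzyme preset %s: rules=%s required=%s",
                enzyme.name, dict(enzyme.subsite_rules), sorted(enzyme.required_subsites))

    chains = None
    results = None
    if "generate" in config.stages:
        chains = generate_ensemble(config.substitution, config.n_chains, seed=config.seed)
        write_chain_strings(chains, out / "chains.txt")
        write_chains_tsv(chains, out / "chains.tsv")
        outputs["chains_txt"] = "chains.txt"
        outputs["chains_tsv"] = "chains.tsv"

    if "digest" in config.stages:
        results = [
            digest(
                c,
                enzyme,
                mode=config.digest_mode,
                site_prob=config.site_prob,
                rng=np.random.default_rng([config.seed, 1, k]),
            )
            for k, c in enumerate(chains)
        ]
        write_products_tsv(results, out / "products.tsv")
        outputs["products_tsv"] = "products.tsv"
        summ = product_summary(results)
        (out / "digest_summary.json").write_text(
            json.dumps(
                {
                    "n_products": summ.n_products,
                    "even_dp_fraction": summ.even_dp_fraction,
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["digest_summary"] = "digest_summary.json"

    if "spectrum" in config.stages:
        products = [p for r in results for p in r.products]
        entries = spectrum_from_products(
            products, label=config.ms.label, adduct=config.ms.adduct
        )
        write_spectrum_tsv(entries, out / "spectrum.tsv")
        outputs["spectrum_tsv"] = "spectrum.tsv"

    if "nmr_stats" in config.stages:
        report = ensemble_report(chains)
        (out / "nmr.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        outputs["nmr_json"] = "nmr.json"

    if "structure" in config.stages:
        sc = config.structure
        deco = _alternating_ac3(sc.dp) if sc.decorate else None
        ribbon = build_ideal_helix(HelixSpec(fold=sc.fold, dp=sc.dp, decoration=deco))
        write_pdb(ribbon, out / "ribbon.pdb")
        outputs["ribbon_pdb"] = "ribbon.pdb"
        records = compute_dihedrals(ribbon)
        with open(out / "linkages.tsv", "w", encoding="utf-8") as fh:
            fh.write("linkage\tphi\tpsi\tsum\tscrew_class\n")
            for r in records:
                fh.write(
                    f"{r.linkage}\t{r.phi:.3f}\t{r.psi:.3f}\t{r.sum:.3f}\t{r.screw_class}\n"
                )
        outputs["linkages_tsv"] = "linkages.tsv"
        lattice = LatticeParams(**sc.lattice)
        posed = build_face_and_dock(
            sc.face, sc.n_cellulose_chains, sc.vacancy, ribbon, lattice=lattice
        )
        write_posed_pdb(posed, out / "posed.pdb")
        outputs["posed_pdb"] = "posed.pdb"
        rep = clash_score(posed, scale=sc.clash_scale)
        bonds = detect_hbonds(posed, d_max=sc.hbond_d_max)
        (out / "contacts.json").write_text(
            json.dumps(
                {
                    "n_clashes": rep.n_clashes,
                    "min_separation": rep.min_separation,
                    "hbond_modes": dict(hbond_mode_tally(bonds)),
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["contacts_json"] = "contacts.json"

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return manifest


def io_roundtrips(outdir: Union[str, Path]) -> dict[str, bool]:
    """Re-read every recognized output in a run directory and re-write it;
    report per-file lossless-roundtrip status.

    Raises a location-bearing error on malformed files.
    """
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {out}")
    manifest = json.loads(manifest_path.read_text())
    report: dict[str, bool] = {}
    import tempfile

    for key, rel in manifest["outputs"].items():
        path = out / rel
        with tempfile.TemporaryDirectory() as tmp:
            copy = Path(tmp) / Path(rel).name
            if rel.endswith("chains.txt"):
                chains = read_chain_strings(path)
                write_chain_strings(chains, copy)
                report[key] = copy.read_bytes() == path.read_bytes()
            elif rel.endswith("chains.tsv"):
                chains = read_chains_tsv(path)
                write_chains_tsv(chains, copy)
                report[key] = copy.read_bytes() == path.read_bytes()
            elif rel.endswith("products.tsv"):
                df = read_products_tsv(path)
                df.to_csv(copy, sep="\t", index=False)
                report[key] = read_products_tsv(copy).equals(df)
            elif rel.endswith("spectrum.tsv"):
                df = read_spectrum_tsv(path)
                df.to_csv(copy, sep="\t", index=False)
                report[key] = read_spectrum_tsv(copy).equals(df)
            elif rel.endswith(".pdb"):
                confs = read_pdb(path)
                n_in = sum(len(c.atoms) for c in confs)
                write_pdb(confs[0], copy)
                n_out = sum(len(c.atoms) for c in read_pdb(copy))
                report[key] = n_out == len(confs[0].atoms) and n_in > 0
            elif rel.endswith(".json"):
                report[key] = isinstance(json.loads(path.read_text()), dict)
            elif rel.endswith(".yaml"):
                report[key] = yaml.safe_load(path.read_text()) is not None
            else:
                report[key] = path.exists()
    return report
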