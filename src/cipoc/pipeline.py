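"""End-to-end screening orchestration.

For every catalyst record in an SDF library: generate a conformer
ensemble (seeded stochastic search), deduplicate it, perceive features and
match every surviving conformer against the catalophore query, keep the
best match per catalyst, rank all hits lexicographically, and export a
per-catalyst QM shortlist (the lowest-energy conformers plus every
matching conformer). Identical config + seed gives byte-identical output
table bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalophore import CGM, load_cgm, match, rank_hits
from .chem import Conformer, EnergyBackend, Molecule, ToyForceField
from .conformers import (SearchLimits, deduplicate, select_for_qm,
                         stochastic_search)
from .errors import CipocError, UsageError
from .io import read_sdf_records, write_sdf_conformers

logger = logging.getLogger("cipoc.screen")


@dataclass
class ScreenConfig:
    library_path: str
    cgm_path: str
    out_dir: str
    seed: int = 0
    iteration_limit: int = 1000
    rejection_limit: int = 1000
    dedup_threshold: float = 0.25    # Å
    n_low: int = 20

    def __post_init__(self) -> None:
        if self.dedup_threshold <= 0 or self.n_low < 0:
            raise UsageError("thresholds must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("library_path", "cgm_path", "out_dir", "seed", "iteration_limit",
                 "rejection_limit", "dedup_threshold", "n_low")}

    def digest(self) -> str:
        """Hash of the parameters that determine the output (paths excluded)."""
        params = {k: getattr(self, k) for k in
                  ("seed", "iteration_limit", "rejection_limit",
                   "dedup_threshold", "n_low")}
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ScreenResult:
    hits: pd.DataFrame        # best match per catalyst, ranked
    details: pd.DataFrame     # one row per matching conformer
    shortlists: dict          # catalyst id -> list of Conformer
    skipped: list = field(default_factory=list)
    run_info: dict = field(default_factory=dict)


def _catalyst_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def screen_library(molecules, cgm: CGM, seed: int = 0,
                   limits: Optional[SearchLimits] = None,
                   backend: Optional[EnergyBackend] = None,
                   dedup_threshold: float = 0.25, n_low: int = 20,
                   names: Optional[list] = None) -> ScreenResult:
    """Screen an in-memory molecule list against a CGM. Library API core."""
    backend = backend or ToyForceField()
    hit_rows, detail_rows, shortlists, skipped = [], [], {}, []
    for idx, mol in enumerate(molecules):
        name = (names[idx] if names else None) or mol.name or f"cat_{idx:04d}"
        try:
            lim = SearchLimits(
                iteration_limit=limits.iteration_limit if limits else 1000,
                rejection_limit=limits.rejection_limit if limits else 1000,
                seed=_catalyst_seed(seed, idx))
            lib = stochastic_search(mol, lim, backend)
            logger.info("%s: search produced %d conformers%s", name, len(lib),
                        " (rigid)" if lib.warning else "")
            lib = deduplicate(lib, dedup_threshold)
            logger.info("%s: %d conformers after dedup", name, len(lib))
            matching_ids = set()
            best = None
            for conf in lib:
                results = match(cgm, conf)
                if not results:
                    continue
                top = results[0]
                matching_ids.add(conf.id)
                detail_rows.append({
                    "catalyst_id": name, "conformer_id": conf.id,
                    "n_matched": top.n_matched, "rmsd": top.rmsd,
                    "energy": conf.energy})
                if (best is None
                        or (-top.n_matched, top.rmsd, conf.energy)
                        < (-best[0].n_matched, best[0].rmsd, best[1].energy)):
                    best = (top, conf)
            if best is not None:
                hit_rows.append({
                    "catalyst_id": name, "conformer_id": best[1].id,
                    "n_matched": best[0].n_matched, "rmsd": best[0].rmsd,
                    "energy": best[1].energy})
            shortlists[name] = select_for_qm(lib, matching_ids, n_low=n_low)
            logger.info("%s: %d matching conformers, %d shortlisted", name,
                        len(matching_ids), len(shortlists[name]))
        except CipocError as exc:
            logger.warning("%s: skipped (%s)", name, exc)
            skipped.append({"catalyst_id": name, "reason": str(exc)})
    hits = rank_hits(hit_rows)
    details = pd.DataFrame(
        detail_rows, columns=["catalyst_id", "conformer_id", "n_matched",
                              "rmsd", "energy"])
    return ScreenResult(hits, details, shortlists, skipped)


def run_screen(config: ScreenConfig) -> ScreenResult:
    """File-based screen: read SDF library + CGM file, write all outputs.

    Outputs in config.out_dir: hits.tsv (ranked best hit per catalyst,
    with a provenance comment header), details.tsv (per matching
    conformer), qm_shortlist.sdf (multi-record, energy/id/catalyst
    properties), run.json (config, seed, version, per-stage counts).
    """
    records = read_sdf_records(Path(config.library_path).read_text())
    cgm = load_cgm(config.cgm_path)
    molecules, names = [], []
    for k, (mol, props) in enumerate(records):
        molecules.append(mol)
        names.append(props.get("id", mol.name or f"cat_{k:04d}"))
    limits = SearchLimits(config.iteration_limit, config.rejection_limit,
                          seed=config.seed)
    result = screen_library(molecules, cgm, seed=config.seed, limits=limits,
                            dedup_threshold=config.dedup_threshold,
                            n_low=config.n_low, names=names)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# cipoc {__version__} | config {config.digest()} | "
              f"seed {config.seed}\n")
    for fname, df in (("hits.tsv", result.hits), ("details.tsv", result.details)):
        body = df.to_csv(sep="\t", index=False, float_format="%.6f")
        (out / fname).write_text(header + body)
    shortlist_chunks = []
    for name, confs in result.shortlists.items():
        if not confs:
            continue
        tagged = [Conformer(c.molecule, c.coordinates, c.energy,
                            id=f"{name}:{c.id}") for c in confs]
        shortlist_chunks.append(write_sdf_conformers(tagged))
    (out / "qm_shortlist.sdf").write_text("".join(shortlist_chunks))
    result.run_info = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_library": len(molecules),
        "n_hits": int(len(result.hits)),
        "n_skipped": len(result.skipped),
        "skipped": result.skipped,
    }
    (out / "run.json").write_text(json.dumps(result.run_info, indent=2) + "\n")
    if result.hits.empty:
        logger.info("screen finished with zero hits")
    return result
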