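"""Catalytic group maps (catalophores) and partial 3D feature matching.

A catalytic group map (CGM) is a pharmacophore-style 3D query derived
from a theozyme: typed features (H-bond donor, H-bond acceptor, aromatic
ring centroid) with tolerance radii, plus excluded-volume spheres at the
substrate atom positions. A candidate conformer matches if a rigid
superposition places at least `min_match` (default two) of its perceived
features within the corresponding tolerance spheres without any heavy
atom entering an exclusion sphere.

Matching enumerates injective, kind-preserving correspondences between
CGM features and conformer features, superposes each candidate
correspondence with the least-squares rigid fit, and keeps those that
satisfy every per-feature tolerance and the steric filter. Results are
ordered lexicographically: more matched features first, then lower RMSD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import periodic
from .chem import Conformer, Molecule
from .errors import UsageError
from .geometry import SuperposeResult, superpose
from .theozyme import TSTemplate

FEATURE_KINDS = ("HBD", "HBA", "AromaticCentroid")
DEFAULT_TOLERANCE = 1.0       # Å
EXCLUSION_VDW_SCALE = 0.8
DEFAULT_MAX_CORRESPONDENCES = 100_000


@dataclass
class Feature:
    kind: str
    position: np.ndarray
    tolerance: Optional[float] = None     # set on CGM features only
    direction: Optional[np.ndarray] = None
    source_atoms: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise UsageError(f"unknown feature kind: {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.tolerance is not None and self.tolerance <= 0:
            raise UsageError("feature tolerance must be positive")


@dataclass
class ExclusionSphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise UsageError("exclusion radius must be positive")


@dataclass
class CGM:
    features: list
    exclusions: list = field(default_factory=list)
    min_match: int = 2
    allow_full: bool = True
    max_correspondences: int = DEFAULT_MAX_CORRESPONDENCES

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise UsageError("a CGM needs at least two features")
        if self.min_match < 2:
            raise UsageError("min_match must be >= 2")


@dataclass
class MatchResult:
    correspondence: dict      # CGM feature index -> conformer feature index
    rmsd: float               # Å over matched features, post-fit
    n_matched: int
    transform: SuperposeResult
    clash: bool = False


def build_cgm(theozyme: TSTemplate, tolerances: Optional[dict] = None,
              min_match: int = 2, allow_full: bool = True) -> CGM:
    """Derive a CGM from a theozyme template.

    One feature per catalytic-site contact position (a double-contact
    acceptor site contributes two HBA features); excluded-volume spheres
    at every substrate heavy atom with radius 0.8 × its van der Waals
    radius — a deliberately lenient steric filter.
    """
    if "HBD" not in theozyme.sites or "HBA" not in theozyme.sites:
        raise UsageError("theozyme must place both an HBD and an HBA site")
    tolerances = tolerances or {}
    features = []
    for kind in ("HBD", "HBA"):
        site = theozyme.sites[kind]
        if not site.positions:
            raise UsageError(f"{kind} site has no placed positions")
        tol = tolerances.get(kind, DEFAULT_TOLERANCE)
        for pos in site.positions:
            features.append(Feature(kind, np.array(pos, float), tolerance=tol,
                                    direction=site.direction))
    exclusions = [
        ExclusionSphere(a.position.copy(),
                        EXCLUSION_VDW_SCALE * periodic.vdw_radius(a.element))
        for a in theozyme.substrate_atoms() if a.is_heavy
    ]
    return CGM(features, exclusions, min_match=min_match, allow_full=allow_full)


def perceive_features(conf: Conformer) -> list:
    """Perceive HBD / HBA / aromatic-centroid features on a conformer.

    HBD: each hydrogen bonded to N or O (position = the H, direction =
    heteroatom→H). HBA: each N or O with formal charge <= 0 (position =
    the heteroatom). AromaticCentroid: centroid of each ring all of whose
    bonds carry the aromatic flag (direction = ring normal). Requires
    connectivity.
    """
    mol = conf.molecule
    if not mol.bonds:
        raise UsageError("feature perception requires bonds (connectivity)")
    coords = conf.coordinates
    features: list[Feature] = []
    for idx, atom in enumerate(mol.atoms):
        if atom.element != "H":
            continue
        for nb in mol.neighbors(idx):
            if mol.atoms[nb].element in ("N", "O"):
                d = coords[idx] - coords[nb]
                n = np.linalg.norm(d)
                direction = d / n if n > 1e-9 else None
                features.append(Feature("HBD", coords[idx].copy(),
                                        direction=direction,
                                        source_atoms=(idx, nb)))
                break
    for idx, atom in enumerate(mol.atoms):
        if atom.element in ("N", "O") and atom.formal_charge <= 0:
            features.append(Feature("HBA", coords[idx].copy(), source_atoms=(idx,)))
    g = nx.Graph()
    g.add_edges_from((b.i, b.j) for b in mol.bonds if b.aromatic)
    for ring in nx.cycle_basis(g):
        if len(ring) < 3:
            continue
        ring = sorted(ring)
        pts = coords[ring]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        features.append(Feature("AromaticCentroid", centroid, direction=vt[2],
                                source_atoms=tuple(ring)))
    return features


def _correspondences(cgm: CGM, conf_features: Sequence[Feature]):
    """Yield injective kind-preserving maps {cgm index -> conformer index}."""
    by_kind_conf: dict[str, list[int]] = {}
    for j, f in enumerate(conf_features):
        by_kind_conf.setdefault(f.kind, []).append(j)
    n = len(cgm.features)
    k_max = n if cgm.allow_full else n - 1
    for k in range(cgm.min_match, k_max + 1):
        for subset in itertools.combinations(range(n), k):
            by_kind_cgm: dict[str, list[int]] = {}
            for i in subset:
                by_kind_cgm.setdefault(cgm.features[i].kind, []).append(i)
            pools = []
            feasible = True
            for kind, idxs in by_kind_cgm.items():
                cands = by_kind_conf.get(kind, [])
                if len(cands) < len(idxs):
                    feasible = False
                    break
                pools.append((idxs, list(itertools.permutations(cands, len(idxs)))))
            if not feasible:
                continue
            for combo in itertools.product(*(perms for _, perms in pools)):
                mapping = {}
                for (idxs, _), perm in zip(pools, combo):
                    mapping.update(zip(idxs, perm))
                yield mapping


def _is_collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    if len(points) <= 2:
        return True
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= tol * max(1.0, s[0]))


def _clashes(placed_heavy: np.ndarray, exclusions) -> bool:
    return any(
        bool(np.any(np.linalg.norm(placed_heavy - s.center, axis=1) < s.radius))
        for s in exclusions
    )


_GAUGE_STEP_DEG = 2.0


def _gauge_free_fit(fit: SuperposeResult, fitted_points: np.ndarray,
                    heavy: np.ndarray, exclusions) -> Optional[SuperposeResult]:
    """Resolve the free axis rotation of a degenerate (collinear) fit.

    Two matched features — or any collinear set — leave the least-squares
    rotation undetermined up to a spin about the matched-segment axis; the
    spin does not move the matched points, so the RMSD and the tolerance
    checks are unaffected, but the rest of the molecule sweeps a circle.
    The steric filter therefore asks whether ANY spin angle clears the
    excluded volume (scanned at 2°), which makes acceptance independent of
    the conformer's input frame. Returns a clash-free transform or None.
    """
    axis = fitted_points[-1] - fitted_points[0]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:  # coincident features: no usable axis, keep the fit as-is
        return fit if not _clashes(heavy @ fit.rotation.T + fit.translation,
                                   exclusions) else None
    u = axis / norm
    center = fitted_points.mean(axis=0)
    for theta in np.arange(0.0, 360.0, _GAUGE_STEP_DEG):
        spin = Rotation.from_rotvec(np.radians(theta) * u).as_matrix()
        # compose x -> spin @ (fit(x) - center) + center
        R = spin @ fit.rotation
        t = center + spin @ (fit.translation - center)
        if not _clashes(heavy @ R.T + t, exclusions):
            return SuperposeResult(R, t, fit.rmsd)
    return None


def match(cgm: CGM, conf: Conformer,
          features: Optional[Sequence[Feature]] = None) -> list:
    """Partial 3D matching of a conformer against a CGM.

    Returns accepted MatchResults sorted by (n_matched desc, rmsd asc).
    An empty list means no match. Enumeration is capped at
    cgm.max_correspondences with a loud diagnostic.
    """
    conf_features = list(features) if features is not None else perceive_features(conf)
    heavy = conf.coordinates[conf.molecule.heavy_indices]
    results = []
    count = 0
    for mapping in _correspondences(cgm, conf_features):
        count += 1
        if count > cgm.max_correspondences:
            warnings.warn(
                f"correspondence enumeration cap ({cgm.max_correspondences}) hit; "
                "match results are truncated", stacklevel=2)
            break
        cgm_idx = sorted(mapping)
        P = np.array([conf_features[mapping[i]].position for i in cgm_idx])
        Q = np.array([cgm.features[i].position for i in cgm_idx])
        fit = superpose(P, Q)
        fitted = fit.apply(P)
        ok = all(
            np.linalg.norm(fitted[r] - Q[r]) <= cgm.features[i].tolerance
            for r, i in enumerate(cgm_idx)
        )
        if not ok:
            continue
        if cgm.exclusions and len(heavy):
            if _is_collinear(P):
                fit2 = _gauge_free_fit(fit, fitted, heavy, cgm.exclusions)
                if fit2 is None:
                    continue
                fit = fit2
            elif _clashes(fit.apply(heavy), cgm.exclusions):
                continue
        results.append(MatchResult({i: mapping[i] for i in cgm_idx},
                                   fit.rmsd, len(cgm_idx), fit))
    results.sort(key=lambda r: (-r.n_matched, r.rmsd))
    return results


def rank_hits(entries: Sequence[dict]) -> pd.DataFrame:
    """Order screening hits lexicographically and assign ranks.

    Sort key: n_matched descending, then rmsd ascending, then conformer
    energy ascending; ties keep input order (stable). Adds a 1-based
    'rank' column.
    """
    df = pd.DataFrame(list(entries))
    if df.empty:
        return pd.DataFrame(columns=["catalyst_id", "conformer_id", "n_matched",
                                     "rmsd", "energy", "rank"])
    required = {"n_matched", "rmsd", "energy"}
    missing = required - set(df.columns)
    if missing:
        raise UsageError(f"hit entries lack required fields: {sorted(missing)}")
    df = df.sort_values(["n_matched", "rmsd", "energy"],
                        ascending=[False, True, True], kind="stable")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------- serialization

def cgm_to_dict(cgm: CGM) -> dict:
    return {
        "features": [
            {"kind": f.kind, "position": [float(v) for v in f.position],
             "tolerance": f.tolerance}
            for f in cgm.features
        ],
        "exclusions": [
            {"center": [float(v) for v in s.center], "radius": float(s.radius)}
            for s in cgm.exclusions
        ],
        "policy": {"min_match": cgm.min_match, "allow_full": cgm.allow_full,
                   "max_correspondences": cgm.max_correspondences},
    }


def cgm_from_dict(d: dict) -> CGM:
    policy = d.get("policy", {})
    return CGM(
        features=[Feature(f["kind"], np.array(f["position"], float),
                          tolerance=f.get("tolerance", DEFAULT_TOLERANCE))
                  for f in d["features"]],
        exclusions=[ExclusionSphere(np.array(s["center"], float), s["radius"])
                    for s in d.get("exclusions", [])],
        min_match=policy.get("min_match", 2),
        allow_full=policy.get("allow_full", True),
        max_correspondences=policy.get("max_correspondences",
                                       DEFAULT_MAX_CORRESPONDENCES),
    )


def save_cgm(cgm: CGM, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cgm_to_dict(cgm), fh, sort_keys=False)


def load_cgm(path) -> CGM:
    with open(path) as fh:
        return cgm_from_dict(yaml.safe_load(fh))
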