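"""Distortion/interaction (activation strain) analysis.

An assembly energy (e.g. a transition state) is decomposed into the
energetic penalty of deforming each fragment from its own relaxed minimum
to its in-assembly geometry (distortion) plus the interaction energy
between the deformed fragments:

    ΔE_total = Σ_i ΔE_dist,i + ΔE_int
    ΔE_dist,i = E_distorted,i − E_relaxed,i
    ΔE_int    = E_assembly − Σ_i E_distorted,i

All energies are caller-supplied (any level of theory) in kcal/mol; the
module never runs an electronic-structure calculation. Fragment
partitioning is the caller's declaration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import UsageError, ValidationError

_DIST_TOL = 1e-6


@dataclass
class FragmentEnergies:
    fragment_id: str
    e_distorted: float   # fragment frozen at its in-assembly geometry
    e_relaxed: float     # fragment at its own minimum

    @property
    def distortion(self) -> float:
        return self.e_distorted - self.e_relaxed


@dataclass
class DIRecord:
    e_assembly: float
    distortions: dict            # fragment id -> ΔE_dist (kcal/mol)
    interaction: float           # ΔE_int
    total: float                 # ΔE_total vs separated relaxed fragments
    path_coordinate: Optional[float] = None

    @property
    def total_distortion(self) -> float:
        return sum(self.distortions.values())


def decompose(e_assembly: float, frags: Sequence[FragmentEnergies],
              path_coordinate: Optional[float] = None) -> DIRecord:
    """Decompose an assembly energy into fragment distortions + interaction.

    The sum rule ΔE_total = Σ ΔE_dist + ΔE_int holds exactly by
    construction. A fragment whose relaxed energy lies above its distorted
    energy (beyond 1e-6 kcal/mol) is inconsistent input and is rejected.
    """
    frags = list(frags)
    if len(frags) < 2:
        raise UsageError("distortion/interaction analysis requires >= 2 fragments")
    ids = [f.fragment_id for f in frags]
    if len(set(ids)) != len(ids):
        raise UsageError("fragment ids must be unique")
    for f in frags:
        if f.distortion < -_DIST_TOL:
            raise ValidationError(
                f"fragment {f.fragment_id!r}: distorted energy lies "
                f"{-f.distortion:.3g} kcal/mol below the relaxed energy")
    distortions = {f.fragment_id: f.distortion for f in frags}
    interaction = e_assembly - sum(f.e_distorted for f in frags)
    # assemble total from the components so the sum rule is exact in floating point
    total = sum(distortions.values()) + interaction
    return DIRecord(e_assembly, distortions, interaction, total, path_coordinate)


def profile_along_path(points) -> list[DIRecord]:
    """Apply decompose along a reaction path.

    `points` is an ordered sequence of (path_coordinate, e_assembly,
    fragments). Coordinates must be strictly monotone.
    """
    points = list(points)
    if not points:
        raise UsageError("empty path")
    coords = [p[0] for p in points]
    diffs = [b - a for a, b in zip(coords, coords[1:])]
    if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
        raise UsageError("path coordinates must be strictly monotone")
    return [decompose(e, frags, path_coordinate=s) for s, e, frags in points]


def profile_table(records: Sequence[DIRecord]) -> pd.DataFrame:
    """Tidy long-format table of decomposition components for plotting."""
    rows = []
    for rec in records:
        base = {"path_coordinate": rec.path_coordinate}
        for fid, d in rec.distortions.items():
            rows.append({**base, "component": f"distortion:{fid}", "energy": d})
        rows.append({**base, "component": "interaction", "energy": rec.interaction})
        rows.append({**base, "component": "total", "energy": rec.total})
    return pd.DataFrame(rows, columns=["path_coordinate", "component", "energy"])


def compare_catalysts(a: DIRecord, b: DIRecord) -> dict:
    """Component-wise differences a − b between two decompositions.

    Both records must carry the same fragment roles. The differences obey
    Δ(total) = Σ Δ(distortion) + Δ(interaction) exactly.
    """
    if set(a.distortions) != set(b.distortions):
        raise UsageError("records have different fragment roles; cannot compare")
    diff = {f"distortion:{fid}": a.distortions[fid] - b.distortions[fid]
            for fid in sorted(a.distortions)}
    diff["interaction"] = a.interaction - b.interaction
    diff["total"] = sum(diff[f"distortion:{fid}"] for fid in sorted(a.distortions)) \
        + diff["interaction"]
    return diff
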