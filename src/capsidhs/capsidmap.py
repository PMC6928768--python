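"""Angular quaternary-structure maps and conservation-based hot spots.

A CapsidMap projects the interface residues of a capsid's asymmetric
unit onto the (φ, ψ) angle space of spherical coordinates about the
capsid center — the radial distance is discarded, so capsids of
different sizes become comparable provided they share the standard
icosahedral orientation. A residue position is conserved in space across
a virus family when the aligned residue of every other member sits
within an angular overlap threshold (default 3° in both angles).

Hot spots are the three-way intersection: interface residues that are
conserved in sequence (strict-identity MSA columns) and conserved in
quaternary position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from capsidhs.structures import AlignmentSet, AsymmetricUnit, Residue

__all__ = [
    "MapPoint", "CapsidMap", "ConservationConfig", "HotSpotResult",
    "ResidueCorrespondence", "project_point", "build_capsidmap",
    "conserved_columns", "column_residue_maps", "align_maps",
    "predict_hotspots", "capsidmap_table",
]

#: heavy backbone atoms excluded from the side-chain centroid
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class MapPoint:
    """One interface residue at its (φ, ψ) angular position (degrees)."""

    residue: tuple[str, int, str]   # (chain class, seq number, icode)
    phi: float                      # [-180, 180)
    psi: float                      # [0, 180]
    res_name: str = ""


@dataclass
class CapsidMap:
    virus_id: str
    points: list[MapPoint]
    orientation_tag: str = "222"

    def lookup(self, chain_class: str, seq_number: int) -> MapPoint | None:
        for p in self.points:
            if p.residue[0] == chain_class and p.residue[1] == seq_number:
                return p
        return None


@dataclass(frozen=True)
class ConservationConfig:
    """Thresholds governing spatial conservation across family members."""

    angle_threshold: float = 3.0      # degrees, applied to φ and ψ separately
    require_all_members: bool = True
    quorum_fraction: float = 1.0      # used when require_all_members=False
    representative: str = "sidechain"  # or "ca"

    def __post_init__(self):
        if self.angle_threshold <= 0:
            raise ValueError("angle_threshold must be positive")
        if not (0.0 < self.quorum_fraction <= 1.0):
            raise ValueError("quorum_fraction must be in (0, 1]")
        if self.representative not in {"sidechain", "ca"}:
            raise ValueError("representative must be 'sidechain' or 'ca'")


@dataclass
class HotSpotResult:
    """The three conservation sets and their intersection."""

    reference_virus: str
    interface_set: dict[str, set]           # virus -> residue keys
    sequence_conserved_set: dict[str, set]  # virus -> residue numbers
    space_conserved_set: dict[str, set]     # virus -> residue keys
    hot_spots: list[tuple[str, int, str]]   # reference-virus keys, sorted
    fold_class: dict[tuple[str, int, str], str] = field(default_factory=dict)

    @property
    def hot_spot_numbers(self) -> list[int]:
        """Distinct residue numbers of the hot spots (reference numbering)."""
        return sorted({k[1] for k in self.hot_spots})


def project_point(coords: Sequence[float], center: Sequence[float] = (0.0, 0.0, 0.0)) -> tuple[float, float]:
    """Spherical-angle projection of a Cartesian point about ``center``.

    Returns (φ, ψ) in degrees with ψ = arccos(v_z/|v|) ∈ [0, 180] the
    polar angle and φ = atan2(v_y, v_x) ∈ [-180, 180) the azimuth. The
    radial distance is discarded. Points on the ±z axis take φ = 0.
    """
    v = np.asarray(coords, dtype=float) - np.asarray(center, dtype=float)
    r = np.linalg.norm(v)
    if r < 1e-12:
        raise ValueError("cannot project the center point (zero-length vector)")
    psi = float(np.degrees(np.arccos(np.clip(v[2] / r, -1.0, 1.0))))
    phi = float(np.degrees(np.arctan2(v[1], v[0])))
    if phi >= 180.0:
        phi -= 360.0
    return phi, psi


def _representative_coords(res: Residue, mode: str) -> np.ndarray:
    heavy = res.heavy_atoms()
    if mode == "ca":
        for a in heavy:
            if a.name.strip() == "CA":
                return a.coords
        return np.mean([a.coords for a in heavy], axis=0)
    side = [a for a in heavy if a.name.strip() not in _BACKBONE]
    if side:
        return np.mean([a.coords for a in side], axis=0)
    # glycine or bead models: fall back to Cα / heavy centroid
    for a in heavy:
        if a.name.strip() == "CA":
            return a.coords
    return np.mean([a.coords for a in heavy], axis=0)


def build_capsidmap(
    au: AsymmetricUnit,
    interface_keys: Iterable[tuple[str, int, str]],
    config: ConservationConfig = ConservationConfig(),
    center: Sequence[float] = (0.0, 0.0, 0.0),
    orientation_tag: str = "222",
) -> CapsidMap:
    """Project the asymmetric unit's interface residues to (φ, ψ).

    ``interface_keys`` are (chain class, seq number, icode) keys, e.g.
    from :func:`capsidhs.interfaces.interface_residue_union`. The
    representative point per residue is the side-chain heavy-atom
    centroid (Cα for glycine), or Cα throughout with
    ``config.representative='ca'``.
    """
    wanted = set(interface_keys)
    points: list[MapPoint] = []
    for sub in au.subunits:
        for res in sub.residues:
            key = (sub.label, res.seq_number, res.insertion_code)
            if key not in wanted:
                continue
            xyz = _representative_coords(res, config.representative)
            phi, psi = project_point(xyz, center)
            points.append(MapPoint(residue=key, phi=phi, psi=psi,
                                   res_name=res.res_name))
    points.sort(key=lambda p: p.residue)
    return CapsidMap(virus_id=au.virus_id, points=points,
                     orientation_tag=orientation_tag)


# ---------------------------------------------------------------------------
# Sequence conservation and MSA correspondence


@dataclass
class ResidueCorrespondence:
    """Per-virus mapping between MSA columns and residue numbers."""

    col_to_resnum: dict[str, dict[int, int]]
    resnum_to_col: dict[str, dict[int, int]]

    def corresponding(self, virus_from: str, resnum: int, virus_to: str) -> int | None:
        col = self.resnum_to_col.get(virus_from, {}).get(resnum)
        if col is None:
            return None
        return self.col_to_resnum.get(virus_to, {}).get(col)


def column_residue_maps(
    aln: AlignmentSet, offsets: Mapping[str, int] | None = None
) -> ResidueCorrespondence:
    """Build column ↔ residue-number maps by counting non-gap positions.

    ``offsets[virus]`` is the author number of that virus's first
    residue (default 1 for every virus).
    """
    offsets = dict(offsets or {})
    col_to_resnum: dict[str, dict[int, int]] = {}
    resnum_to_col: dict[str, dict[int, int]] = {}
    for virus, seq in aln.sequences.items():
        start = offsets.get(virus, 1)
        c2r: dict[int, int] = {}
        r2c: dict[int, int] = {}
        count = 0
        for col, ch in enumerate(seq):
            if ch != "-":
                num = start + count
                c2r[col] = num
                r2c[num] = col
                count += 1
        col_to_resnum[virus] = c2r
        resnum_to_col[virus] = r2c
    return ResidueCorrespondence(col_to_resnum, resnum_to_col)


def conserved_columns(
    aln: AlignmentSet, offsets: Mapping[str, int] | None = None
) -> tuple[list[int], dict[str, set[int]]]:
    """Strict-identity conserved MSA columns.

    A column is conserved when every sequence carries the same residue
    and none has a gap. Returns the column indices and, per virus, the
    set of residue numbers those columns map to.
    """
    if not aln.sequences:
        raise ValueError("empty alignment")
    corr = column_residue_maps(aln, offsets)
    seqs = list(aln.sequences.values())
    cols: list[int] = []
    for col in range(aln.n_columns):
        chars = {s[col] for s in seqs}
        if len(chars) == 1 and "-" not in chars:
            cols.append(col)
    per_virus = {
        virus: {corr.col_to_resnum[virus][c] for c in cols}
        for virus in aln.sequences
    }
    return cols, per_virus


# ---------------------------------------------------------------------------
# Map alignment (space conservation)


def _circular_diff(a: float, b: float) -> float:
    """Minimal absolute angular difference on the circle, degrees."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def align_maps(
    maps: Sequence[CapsidMap],
    correspondence: ResidueCorrespondence,
    config: ConservationConfig = ConservationConfig(),
    reference: str | None = None,
) -> dict[str, set[tuple[str, int, str]]]:
    """Space-conserved residue sets across two or more CapsidMaps.

    A residue of the reference virus is space-conserved when, for every
    other member (or a quorum of them), the MSA-corresponding residue of
    the same chain class is present in that member's map within the
    angular threshold in both φ (on the circle) and ψ. Returns per-virus
    sets of residue keys; the reference set is the conserved set, the
    other sets its aligned counterparts.
    """
    if len(maps) < 2:
        raise ValueError("map alignment needs at least two family members")
    tags = {m.orientation_tag for m in maps}
    if len(tags) > 1:
        raise ValueError(f"mismatched orientation tags: {sorted(tags)}")
    ref_id = reference or maps[0].virus_id
    ref_map = next((m for m in maps if m.virus_id == ref_id), None)
    if ref_map is None:
        raise KeyError(f"no map for reference virus {ref_id!r}")
    others = [m for m in maps if m.virus_id != ref_id]

    thr = config.angle_threshold
    need = len(others) if config.require_all_members else max(
        1, int(np.ceil(config.quorum_fraction * len(others)))
    )

    out: dict[str, set] = {m.virus_id: set() for m in maps}
    for point in ref_map.points:
        cls, num, icode = point.residue
        matches: list[tuple[str, tuple[str, int, str]]] = []
        for om in others:
            partner_num = correspondence.corresponding(ref_id, num, om.virus_id)
            if partner_num is None:
                continue
            partner = om.lookup(cls, partner_num)
            if partner is None:
                continue
            if (_circular_diff(point.phi, partner.phi) <= thr
                    and abs(point.psi - partner.psi) <= thr):
                matches.append((om.virus_id, partner.residue))
        if len(matches) >= need:
            out[ref_id].add(point.residue)
            for virus, key in matches:
                out[virus].add(key)
    return out


def predict_hotspots(
    interface_sets: Mapping[str, set],
    seq_conserved_sets: Mapping[str, set],
    space_conserved_sets: Mapping[str, set],
    reference: str,
    fold_annotation: Mapping[tuple[str, int, str], str] | None = None,
) -> HotSpotResult:
    """Three-way intersection: interface ∩ sequence ∩ space conservation.

    All sets are read in the reference virus's keying: interface and
    space sets hold (chain class, seq number, icode) keys, the sequence
    set holds residue numbers. The hot spots are reported in reference
    numbering, annotated with interface fold class when provided.
    """
    for name, sets in (("interface", interface_sets),
                       ("sequence-conserved", seq_conserved_sets),
                       ("space-conserved", space_conserved_sets)):
        if reference not in sets:
            raise KeyError(f"reference virus {reference!r} missing from {name} sets")
    iface = interface_sets[reference]
    seq_nums = seq_conserved_sets[reference]
    space = space_conserved_sets[reference]
    hot = sorted(k for k in iface if k[1] in seq_nums and k in space)
    folds = {}
    if fold_annotation:
        folds = {k: fold_annotation[k] for k in hot if k in fold_annotation}
    return HotSpotResult(
        reference_virus=reference,
        interface_set={v: set(s) for v, s in interface_sets.items()},
        sequence_conserved_set={v: set(s) for v, s in seq_conserved_sets.items()},
        space_conserved_set={v: set(s) for v, s in space_conserved_sets.items()},
        hot_spots=hot,
        fold_class=folds,
    )


def capsidmap_table(cmap: CapsidMap) -> pd.DataFrame:
    """CapsidMap as a tidy table (virus, chain, resnum, resname, φ, ψ)."""
    return pd.DataFrame([
        {"virus": cmap.virus_id, "chain": p.residue[0], "resnum": p.residue[1],
         "resname": p.res_name, "phi_deg": p.phi, "psi_deg": p.psi}
        for p in cmap.points
    ])
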