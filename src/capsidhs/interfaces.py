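"""Interface-residue detection, symmetry-fold classification and SASA/BSA.

An interface residue of a subunit pair is a residue with at least one
heavy atom within a distance cutoff (default 4.5 Å, the conventional
close-contact radius) of a heavy atom of the partner subunit. Contact
search uses a k-d tree; results are identical to the all-pairs
computation by construction (the tree is exact) and this is asserted by
property tests.

Per-residue surface quantities follow the Shrake–Rupley sphere-point
construction with a 1.4 Å water probe: SASA in the complex, SASA of the
subunit alone, and BSA = SASA(isolated) − SASA(complex). The number of
distinct partner residues in contact is reported as ``num_contacts``
(the "NumInt" of interface contact tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from capsidhs.structures import AsymmetricUnit, Residue, Subunit
from capsidhs.symmetry import (
    CapsidAssembly,
    FOLD_IDENTITY,
    relative_operator,
)

__all__ = [
    "ContactCriterion", "ResidueContact", "InterfacePair", "ResidueProfile",
    "find_interfaces", "interface_residue_union", "classify_interface_fold",
    "compute_sasa", "residue_profile", "VDW_RADII", "interface_table",
    "FOLD_QUASI",
]

FOLD_QUASI = "quasi"

#: Van der Waals radii (Å), Bondi 1964 values for common elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "MG": 1.73, "CA": 2.31, "FE": 2.00, "NA": 2.27,
    "K": 2.75, "MN": 2.00, "CU": 1.40,
}


@dataclass(frozen=True)
class ContactCriterion:
    """Distance criterion defining a close intermolecular contact."""

    cutoff: float = 4.5          # Å, heavy-atom to heavy-atom
    heavy_atoms_only: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class ResidueContact:
    """One interface residue: its key, partners and atomic contact count."""

    key: tuple[str, int, str]           # (subunit label, seq number, icode)
    res_name: str
    partners: tuple[tuple[str, int, str], ...]
    n_atomic: int

    @property
    def num_contacts(self) -> int:
        return len(self.partners)


@dataclass
class InterfacePair:
    """Interface between two subunits, with residue-level contact lists."""

    subunit_i: str
    subunit_j: str
    residues_i: list[ResidueContact]
    residues_j: list[ResidueContact]
    fold_class: str | None = None
    contact_centroid: np.ndarray | None = None


@dataclass
class ResidueProfile:
    """Table-1-style per-residue geometry: SASA, BSA and contact count."""

    key: tuple[str, int, str]
    res_name: str
    sasa_complex: float   # Å²
    sasa_isolated: float  # Å²
    bsa: float            # Å², clamped at 0
    num_contacts: int


def _subunit_list(complex_like) -> list[Subunit]:
    if isinstance(complex_like, CapsidAssembly):
        return complex_like.subunits
    if isinstance(complex_like, AsymmetricUnit):
        return complex_like.subunits
    return list(complex_like)


def _atom_table(subunits: Sequence[Subunit], heavy_only: bool):
    """Flatten to arrays: coords, subunit index, residue index within subunit."""
    coords, sub_idx, res_idx = [], [], []
    for si, sub in enumerate(subunits):
        for ri, res in enumerate(sub.residues):
            atoms = res.heavy_atoms() if heavy_only else res.atoms
            for a in atoms:
                coords.append(a.coords)
                sub_idx.append(si)
                res_idx.append(ri)
    if not coords:
        return np.empty((0, 3)), np.empty(0, int), np.empty(0, int)
    return np.array(coords), np.array(sub_idx), np.array(res_idx)


def find_interfaces(
    complex_like,
    criterion: ContactCriterion = ContactCriterion(),
    focus: Sequence[str] | None = None,
) -> list[InterfacePair]:
    """Detect all inter-subunit interfaces in a complex.

    ``complex_like`` may be a :class:`CapsidAssembly` (interfaces are
    then fold-classified), an :class:`AsymmetricUnit`, or a plain list
    of subunits (e.g. a dimer). ``focus`` restricts output to pairs
    where at least one member's label is in the given set. Pairs with no
    contacting residues are omitted.
    """
    subunits = _subunit_list(complex_like)
    if not subunits:
        raise ValueError("empty complex: no subunits")
    labels = [s.label for s in subunits]
    if len(set(labels)) != len(labels):
        raise ValueError("subunit labels must be unique")
    focus_set = set(focus) if focus is not None else None

    coords, sub_idx, res_idx = _atom_table(subunits, criterion.heavy_atoms_only)
    if len(coords) == 0:
        return []
    tree = cKDTree(coords)
    pairs = tree.query_pairs(criterion.cutoff, output_type="ndarray")

    # contacts[(si, sj)][(ri, rj)] = atomic contact count; midpoint accumulator
    contacts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    centroids: dict[tuple[int, int], list] = {}
    for a, b in pairs:
        sa, sb = int(sub_idx[a]), int(sub_idx[b])
        if sa == sb:
            continue
        if sa > sb:
            a, b = b, a
            sa, sb = sb, sa
        key = (sa, sb)
        rkey = (int(res_idx[a]), int(res_idx[b]))
        contacts.setdefault(key, {})
        contacts[key][rkey] = contacts[key].get(rkey, 0) + 1
        centroids.setdefault(key, []).append((coords[a] + coords[b]) / 2.0)

    result: list[InterfacePair] = []
    for (sa, sb) in sorted(contacts):
        sub_a, sub_b = subunits[sa], subunits[sb]
        if focus_set is not None and not ({sub_a.label, sub_b.label} & focus_set):
            continue
        res_pairs = contacts[(sa, sb)]

        def _side(own: Subunit, other: Subunit, flip: bool) -> list[ResidueContact]:
            per_res: dict[int, dict] = {}
            for (ra, rb), n in res_pairs.items():
                ri, rj = (rb, ra) if flip else (ra, rb)
                rec = per_res.setdefault(ri, {"partners": set(), "n": 0})
                pr = other.residues[rj]
                rec["partners"].add((other.label, pr.seq_number, pr.insertion_code))
                rec["n"] += n
            out = []
            for ri in sorted(per_res):
                res = own.residues[ri]
                out.append(ResidueContact(
                    key=(own.label, res.seq_number, res.insertion_code),
                    res_name=res.res_name,
                    partners=tuple(sorted(per_res[ri]["partners"])),
                    n_atomic=per_res[ri]["n"],
                ))
            return out

        pair = InterfacePair(
            subunit_i=sub_a.label,
            subunit_j=sub_b.label,
            residues_i=_side(sub_a, sub_b, flip=False),
            residues_j=_side(sub_b, sub_a, flip=True),
            contact_centroid=np.mean(centroids[(sa, sb)], axis=0),
        )
        if isinstance(complex_like, CapsidAssembly):
            pair.fold_class = classify_interface_fold(pair, complex_like)
        result.append(pair)
    return result


def _chain_class(label: str) -> str:
    return label.rstrip("0123456789")


def interface_residue_union(
    pairs: Iterable[InterfacePair], subunit_class: str | None = None
) -> set[tuple[str, int, str]]:
    """Union of interface residues in asymmetric-unit numbering.

    Keys are mapped from subunit labels (e.g. "A12") back to the chain
    class ("A"). With ``subunit_class`` given, only residues of that
    class are returned.
    """
    out: set[tuple[str, int, str]] = set()
    for pair in pairs:
        for rc in list(pair.residues_i) + list(pair.residues_j):
            cls = _chain_class(rc.key[0])
            if subunit_class is not None and cls != subunit_class:
                continue
            out.add((cls, rc.key[1], rc.key[2]))
    return out


def classify_interface_fold(
    pair: InterfacePair,
    assembly: CapsidAssembly,
    axis_angle_tol_deg: float = 15.0,
) -> str:
    """Symmetry-fold class of an interface: 2-fold, 3-fold, 5-fold or quasi.

    The class is the fold of the relative group operator between the two
    subunits. Contacts whose relative operator is the identity (chains of
    one asymmetric unit) are quasi-equivalent, as are cross-class contacts
    whose contact centroid does not sit near the relative operator's
    rotation axis — those do not wrap a true icosahedral axis.
    """
    if pair.subunit_i == pair.subunit_j:
        raise ValueError("a subunit has no interface with itself")
    op = relative_operator(assembly, pair.subunit_i, pair.subunit_j)
    if op.fold == FOLD_IDENTITY:
        return FOLD_QUASI
    ci, _ = assembly.generator_map[pair.subunit_i]
    cj, _ = assembly.generator_map[pair.subunit_j]
    if ci != cj and pair.contact_centroid is not None and op.axis is not None:
        c = pair.contact_centroid
        norm = np.linalg.norm(c)
        if norm > 1e-9:
            cosang = abs(float(np.dot(c / norm, op.axis)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > axis_angle_tol_deg:
                return FOLD_QUASI
    return op.fold


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    subunits: Sequence[Subunit],
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> dict[tuple[str, int, str], float]:
    """Per-residue solvent-accessible surface area (Å²).

    Shrake–Rupley: each heavy atom's sphere of radius r_vdw + probe is
    sampled at ``n_points`` deterministic points; points inside any
    neighbor's expanded sphere are buried. Residue SASA is the sum over
    its heavy atoms. Hydrogens are ignored.
    """
    radii = radii or VDW_RADII
    atoms: list[tuple[tuple[str, int, str], float, np.ndarray]] = []
    unknown: list[str] = []
    for sub in subunits:
        for res in sub.residues:
            key = (sub.label, res.seq_number, res.insertion_code)
            for a in res.heavy_atoms():
                r = radii.get(a.element.upper())
                if r is None:
                    unknown.append(f"{sub.label}/{res.seq_number}/{a.name}({a.element})")
                else:
                    atoms.append((key, r, a.coords))
    if unknown:
        raise KeyError(f"no van der Waals radius for atoms: {unknown}")
    if not atoms:
        return {}

    keys = [a[0] for a in atoms]
    rads = np.array([a[1] for a in atoms]) + probe
    xyz = np.array([a[2] for a in atoms])
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    max_r = rads.max()
    sasa: dict[tuple[str, int, str], float] = {}
    for i in range(len(atoms)):
        ri = rads[i]
        neighbors = tree.query_ball_point(xyz[i], ri + max_r)
        neighbors = [j for j in neighbors if j != i
                     and np.linalg.norm(xyz[j] - xyz[i]) < ri + rads[j]]
        pts = xyz[i] + ri * sphere
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_r = rads[neighbors]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = 4.0 * np.pi * ri * ri * frac
        sasa[keys[i]] = sasa.get(keys[i], 0.0) + area
    # residues whose atoms were all skipped do not appear; ensure zero entries
    for sub in subunits:
        for res in sub.residues:
            sasa.setdefault((sub.label, res.seq_number, res.insertion_code), 0.0)
    return sasa


def residue_profile(
    dimer: Sequence[Subunit],
    residue_key: tuple[str, int, str],
    criterion: ContactCriterion = ContactCriterion(),
    probe: float = 1.4,
    n_points: int = 960,
) -> ResidueProfile:
    """SASA/BSA/NumInt profile of one residue in a two-subunit complex."""
    dimer = list(dimer)
    if len(dimer) != 2:
        raise ValueError("residue_profile expects exactly two subunits")
    label, num, icode = residue_key
    owner = next((s for s in dimer if s.label == label), None)
    if owner is None:
        raise KeyError(f"no subunit labeled {label!r} in dimer")
    res = next(
        (r for r in owner.residues
         if r.seq_number == num and r.insertion_code == icode),
        None,
    )
    if res is None:
        raise KeyError(f"residue {residue_key} not found")

    sasa_cx = compute_sasa(dimer, probe=probe, n_points=n_points)[residue_key]
    sasa_iso = compute_sasa([owner], probe=probe, n_points=n_points)[residue_key]
    bsa = sasa_iso - sasa_cx
    if bsa < -0.5:
        raise AssertionError(
            f"BSA {bsa:.2f} Å² below discretization tolerance for {residue_key}"
        )
    num_contacts = 0
    for pair in find_interfaces(dimer, criterion):
        for rc in list(pair.residues_i) + list(pair.residues_j):
            if rc.key == residue_key:
                num_contacts = max(num_contacts, rc.num_contacts)
    return ResidueProfile(
        key=residue_key,
        res_name=res.res_name,
        sasa_complex=sasa_cx,
        sasa_isolated=sasa_iso,
        bsa=max(bsa, 0.0),
        num_contacts=num_contacts,
    )


def interface_table(pairs: Iterable[InterfacePair], virus_id: str = "") -> pd.DataFrame:
    """Interface residues as a tidy table (contact-table semantics)."""
    rows = []
    for p in pairs:
        for side, contacts in (("i", p.residues_i), ("j", p.residues_j)):
            for rc in contacts:
                rows.append({
                    "virus": virus_id,
                    "pair": f"{p.subunit_i}-{p.subunit_j}",
                    "fold": p.fold_class or "",
                    "subunit": rc.key[0],
                    "resnum": rc.key[1],
                    "resname": rc.res_name,
                    "num_contacts": rc.num_contacts,
                    "atomic_contacts": rc.n_atomic,
                })
    return pd.DataFrame(rows)
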