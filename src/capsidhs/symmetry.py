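"""Icosahedral rotation group, capsid assembly and subunit labeling.

An icosahedral capsid is generated from its asymmetric unit by the 60
proper rotations of the icosahedral group I. The group is built from two
generators — a 5-fold about an icosahedron vertex and a 2-fold about a
coordinate axis, in the standard setting that puts the three mutually
perpendicular 2-fold axes on x, y, z (the VIPERdb/PDB icosahedral
convention) — and closed numerically, so construction errors cannot hide
in a hard-coded table.

Rotation folds are classified from the trace (trace = 1 + 2 cos θ):
θ = 0° identity, 180° 2-fold, 120° 3-fold, 72°/144° 5-fold. Conjugacy
class sizes are {1, 15, 20, 24}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from capsidhs.structures import AsymmetricUnit, Subunit

__all__ = [
    "SymmetryOperator", "IcosahedralGroup", "CapsidAssembly",
    "generate_group", "classify_operator", "assemble_capsid",
    "relative_operator", "group_to_json", "group_to_biomt",
]

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0

#: Frobenius tolerance for orthogonality and group-membership checks.
MATRIX_TOL = 1e-8

FOLD_IDENTITY = "identity"
FOLD_2 = "2-fold"
FOLD_3 = "3-fold"
FOLD_5 = "5-fold"

_ANGLE_TO_FOLD = {0: FOLD_IDENTITY, 180: FOLD_2, 120: FOLD_3,
                  72: FOLD_5, 144: FOLD_5}


@dataclass(frozen=True)
class SymmetryOperator:
    index: int
    matrix: np.ndarray
    fold: str
    axis: np.ndarray | None  # unit vector; None for identity

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))

    @property
    def angle_deg(self) -> float:
        tr = float(np.trace(self.matrix))
        return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


@dataclass
class IcosahedralGroup:
    operators: list[SymmetryOperator]
    orientation_tag: str = "222"

    def __post_init__(self):
        if len(self.operators) != 60:
            raise ValueError(
                f"icosahedral rotation group has 60 elements, got {len(self.operators)}"
            )

    def matrices(self) -> np.ndarray:
        return np.stack([op.matrix for op in self.operators])

    def find(self, matrix: np.ndarray, tol: float = 1e-6) -> SymmetryOperator:
        """Return the group element numerically equal to ``matrix``."""
        diffs = np.abs(self.matrices() - matrix[None]).max(axis=(1, 2))
        i = int(np.argmin(diffs))
        if diffs[i] > tol:
            raise ValueError("matrix is not a member of the group")
        return self.operators[i]


@dataclass
class CapsidAssembly:
    """A full capsid: 60 symmetry copies of each asymmetric-unit chain."""

    subunits: list[Subunit]
    t_number: int
    generator_map: dict[str, tuple[str, int]]  # label -> (source chain, op index)
    group: IcosahedralGroup

    def subunit(self, label: str) -> Subunit:
        for s in self.subunits:
            if s.label == label:
                return s
        raise KeyError(f"no subunit labeled {label!r}")


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def classify_operator(matrix: np.ndarray) -> tuple[str, np.ndarray | None]:
    """Classify a rotation matrix by fold; return (fold, unit axis).

    The axis is the +1 eigenvector, oriented so its z component is
    positive (ties broken toward positive x, then positive y); the
    identity has no axis.
    """
    M = np.asarray(matrix, dtype=float)
    if np.abs(M.T @ M - np.eye(3)).max() > 1e-6 or np.linalg.det(M) < 0:
        raise ValueError("not a proper rotation matrix")
    tr = float(np.trace(M))
    angle = float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
    best = min(_ANGLE_TO_FOLD, key=lambda a: abs(a - angle))
    if abs(best - angle) > 0.5:
        raise ValueError(f"rotation angle {angle:.3f}° is not icosahedral")
    fold = _ANGLE_TO_FOLD[best]
    if fold == FOLD_IDENTITY:
        return fold, None
    w, v = np.linalg.eigh((M + M.T) / 2.0)
    axis = v[:, int(np.argmax(w))]
    # orientation convention: positive z, then x, then y
    for comp in (2, 0, 1):
        if abs(axis[comp]) > 1e-9:
            if axis[comp] < 0:
                axis = -axis
            break
    return fold, axis / np.linalg.norm(axis)


def generate_group(orientation_tag: str = "222") -> IcosahedralGroup:
    """Generate the 60-element icosahedral rotation group by closure.

    In the ``"222"`` setting the icosahedron vertices sit at the cyclic
    permutations of (0, ±1, ±φ) and the three perpendicular 2-fold axes
    coincide with x, y, z. Generators: a 72° rotation about the vertex
    (0, 1, φ) and a 180° rotation about z.
    """
    if orientation_tag != "222":
        raise ValueError(f"unknown orientation_tag: {orientation_tag!r}")
    g5 = _rotation_matrix((0.0, 1.0, GOLDEN_RATIO), 72.0)
    g2 = _rotation_matrix((0.0, 0.0, 1.0), 180.0)

    mats: list[np.ndarray] = [np.eye(3)]

    def _find(M: np.ndarray) -> bool:
        return any(np.abs(M - O).max() < 1e-6 for O in mats)

    frontier = [np.eye(3)]
    while frontier:
        new: list[np.ndarray] = []
        for F in frontier:
            for G in (g5, g2):
                M = G @ F
                if not _find(M):
                    mats.append(M)
                    new.append(M)
        frontier = new
        if len(mats) > 120:
            raise RuntimeError("group closure did not terminate at order 60")

    # deterministic ordering: identity first, then by (angle, axis) lexicographic
    def _sort_key(M: np.ndarray):
        fold, axis = classify_operator(M)
        tr = float(np.trace(M))
        ax = tuple(np.round(axis, 9)) if axis is not None else (2.0, 2.0, 2.0)
        return (-tr, ax, tuple(np.round(M.ravel(), 9)))

    mats.sort(key=_sort_key)
    operators = []
    for i, M in enumerate(mats):
        fold, axis = classify_operator(M)
        operators.append(SymmetryOperator(index=i, matrix=M, fold=fold, axis=axis))
    group = IcosahedralGroup(operators=operators, orientation_tag=orientation_tag)
    _validate_group(group)
    return group


def _validate_group(group: IcosahedralGroup) -> None:
    mats = group.matrices()
    for M in mats:
        if np.abs(M.T @ M - np.eye(3)).max() > MATRIX_TOL:
            raise RuntimeError("non-orthogonal operator in group")
        if abs(np.linalg.det(M) - 1.0) > MATRIX_TOL:
            raise RuntimeError("improper operator in group")
    folds = [op.fold for op in group.operators]
    counts = {f: folds.count(f) for f in set(folds)}
    expected = {FOLD_IDENTITY: 1, FOLD_2: 15, FOLD_3: 20, FOLD_5: 24}
    if counts != expected:
        raise RuntimeError(f"wrong conjugacy class sizes: {counts}")


def axes_of_fold(group: IcosahedralGroup, fold: str) -> np.ndarray:
    """Distinct rotation axes of a given fold (unit vectors, deduplicated)."""
    axes: list[np.ndarray] = []
    for op in group.operators:
        if op.fold != fold or op.axis is None:
            continue
        if not any(abs(float(np.dot(a, op.axis))) > 1.0 - 1e-9 for a in axes):
            axes.append(op.axis)
    return np.array(axes)


def assemble_capsid(au: AsymmetricUnit, group: IcosahedralGroup) -> CapsidAssembly:
    """Apply all 60 operators to every asymmetric-unit chain.

    Labels are class letter (the source chain) plus copy index taken
    from the operator index, 1-based: chain "A" under operator 0 (the
    identity) becomes "A1". A T=3 asymmetric unit of 3 chains yields
    180 subunits.
    """
    if not au.subunits:
        raise ValueError("empty asymmetric unit")
    subunits: list[Subunit] = []
    generator_map: dict[str, tuple[str, int]] = {}
    for chain in au.subunits:
        for op in group.operators:
            label = f"{chain.label}{op.index + 1}"
            subunits.append(chain.transformed(op.matrix, label=label))
            generator_map[label] = (chain.label, op.index)
    return CapsidAssembly(
        subunits=subunits,
        t_number=len(au.subunits),
        generator_map=generator_map,
        group=group,
    )


def relative_operator(
    assembly: CapsidAssembly, label_i: str, label_j: str
) -> SymmetryOperator:
    """The group element carrying subunit i's frame onto subunit j's.

    For subunits generated as R_i·chain and R_j·chain the relation is
    R_j·R_i⁻¹, returned as the matching (classified) group member.
    """
    for lab in (label_i, label_j):
        if lab not in assembly.generator_map:
            raise KeyError(f"unknown subunit label {lab!r}")
    _, oi = assembly.generator_map[label_i]
    _, oj = assembly.generator_map[label_j]
    Ri = assembly.group.operators[oi].matrix
    Rj = assembly.group.operators[oj].matrix
    return assembly.group.find(Rj @ Ri.T)


# ---------------------------------------------------------------------------
# Export


def group_to_json(group: IcosahedralGroup) -> str:
    rows = []
    for op in group.operators:
        rows.append({
            "index": op.index,
            "matrix": [round(float(x), 12) for x in op.matrix.ravel()],
            "fold": op.fold,
            "axis": [round(float(x), 12) for x in op.axis] if op.axis is not None else None,
        })
    return json.dumps(rows, indent=1)


def group_to_biomt(group: IcosahedralGroup) -> str:
    """Operators as PDB REMARK 350 BIOMT lines (zero translation)."""
    lines = []
    for op in group.operators:
        for row in range(3):
            m = op.matrix[row]
            lines.append(
                f"REMARK 350   BIOMT{row + 1} {op.index + 1:3d}"
                f"{m[0]:10.6f}{m[1]:10.6f}{m[2]:10.6f}{0.0:15.5f}"
            )
    return "\n".join(lines) + "\n"
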