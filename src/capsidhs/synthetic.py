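"""Synthetic inputs with known ground truth.

Two generators drive the test suite and the acceptance checks:

* :func:`make_toy_family` builds a family of coarse Cα-bead capsids with
  planted interface residues, planted sequence-conserved alignment
  columns and planted space-conserved positions, returning the ground
  truth alongside the data. Planted interface residues are placed a
  fixed perpendicular distance (1.8 Å) from a 2-fold symmetry axis, so
  after assembly their own 2-fold image lies 3.6 Å away — inside the
  4.5 Å contact cutoff — regardless of where along the axis they sit.
  Non-interface residues are wound into a compact helix deep in the
  asymmetric unit's angular interior at a much larger radius, so no
  symmetry image comes near them. Space-conserved residues keep the same
  angular position across members up to a bounded noise; other interface
  residues are moved to a *different* 2-fold axis in the non-reference
  members (≥ 36° away, far beyond any realistic overlap threshold)
  while remaining genuine interface residues.

* :func:`sample_umbrella` draws umbrella-window samples *exactly* from
  the biased Boltzmann density ∝ exp(−(U(ξ) + w(ξ))/k_BT) by inverse-CDF
  sampling on a fine grid — no Markov-chain error, so WHAM must recover
  U up to statistical noise.

Both are fully deterministic under their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

from capsidhs.structures import AsymmetricUnit, Atom, Residue, Subunit, WindowSeries
from capsidhs.symmetry import (
    FOLD_2,
    IcosahedralGroup,
    assemble_capsid,
    axes_of_fold,
    generate_group,
)
from capsidhs.wham import BiasPotential, KB_KCAL

__all__ = [
    "ToyFamilySpec", "ToyFamilyTruth", "SyntheticPotentialSpec",
    "make_toy_family", "sample_umbrella",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = "".join(sorted(_AA3))

_CHAIN_LETTERS = "ABCD"

# geometry constants (Å) — see docs/methods.md for the derivation
_AXIS_OFFSET = 1.8        # perpendicular distance of a planted bead from its axis
_CONTACT_RADIUS_CAP = 40.0
_SAFE_RADIUS = 110.0      # radial start of the non-interface helix
_CHAIN_RADIAL_GAP = 45.0  # radial stagger between chains' helices
_HELIX_RADIUS = 5.0
_HELIX_RISE = 0.5
_HELIX_PER_TURN = 8


@dataclass(frozen=True)
class ToyFamilySpec:
    """Parameters of a planted-truth toy capsid family."""

    n_members: int = 4
    t_number: int = 3
    residues_per_chain: int = 30
    planted_interface: frozenset[int] = frozenset({3, 4, 5, 11, 12, 20})
    planted_seq_conserved: frozenset[int] = frozenset({3, 5, 11, 20, 25, 28})
    planted_space_conserved: frozenset[int] = frozenset({3, 5, 11, 20})
    angular_noise: float = 1.0   # degrees, applied per angle in non-reference members
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_interface", frozenset(self.planted_interface))
        object.__setattr__(self, "planted_seq_conserved", frozenset(self.planted_seq_conserved))
        object.__setattr__(self, "planted_space_conserved", frozenset(self.planted_space_conserved))
        if self.n_members < 1:
            raise ValueError("n_members must be ≥ 1")
        if not (1 <= self.t_number <= len(_CHAIN_LETTERS)):
            raise ValueError(f"t_number must be in 1..{len(_CHAIN_LETTERS)}")
        if self.angular_noise < 0:
            raise ValueError("angular_noise must be ≥ 0")
        if not self.planted_space_conserved <= self.planted_interface:
            raise ValueError("planted_space_conserved must be ⊆ planted_interface")
        all_planted = self.planted_interface | self.planted_seq_conserved
        if all_planted and (min(all_planted) < 1
                            or max(all_planted) > self.residues_per_chain):
            raise ValueError("planted residue indices exceed chain length")
        n_safe = self.residues_per_chain - len(self.planted_interface)
        if n_safe < 1:
            raise ValueError("chain has no room for non-interface residues")


@dataclass
class ToyFamilyTruth:
    """Ground truth returned with the family; keys are in AU numbering."""

    interface_keys: set[tuple[str, int, str]]
    seq_conserved_numbers: set[int]
    space_conserved_keys: set[tuple[str, int, str]]
    hot_spot_keys: set[tuple[str, int, str]]

    @property
    def hot_spot_numbers(self) -> set[int]:
        return {k[1] for k in self.hot_spot_keys}


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(axis, helper))) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _direction_from_angles(phi_deg: float, psi_deg: float) -> np.ndarray:
    phi, psi = np.radians(phi_deg), np.radians(psi_deg)
    return np.array([
        np.sin(psi) * np.cos(phi), np.sin(psi) * np.sin(phi), np.cos(psi)
    ])


def _angles_of(v: np.ndarray) -> tuple[float, float]:
    r = np.linalg.norm(v)
    psi = float(np.degrees(np.arccos(np.clip(v[2] / r, -1.0, 1.0))))
    phi = float(np.degrees(np.arctan2(v[1], v[0])))
    return phi, psi


def _contact_bead(direction: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Place a bead along ``direction`` so it sits ≤ 1.8 Å off ``axis``."""
    u = direction / np.linalg.norm(direction)
    sin_a = float(np.linalg.norm(np.cross(u, axis)))
    t = _CONTACT_RADIUS_CAP if sin_a < 1e-9 else min(
        _CONTACT_RADIUS_CAP, _AXIS_OFFSET / sin_a
    )
    return t * u


def _tilted_direction(axis: np.ndarray, tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    e1, e2 = _orthonormal_frame(axis)
    t = np.radians(tilt_deg)
    a = np.radians(azimuth_deg)
    return np.cos(t) * axis + np.sin(t) * (np.cos(a) * e1 + np.sin(a) * e2)


def _safe_direction(group: IcosahedralGroup) -> np.ndarray:
    """Direction maximizing the minimal symmetry-image distance (per unit r)."""
    n = 2000
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    mats = group.matrices()[1:]  # skip identity (sorted first)
    images = np.einsum("oij,pj->opi", mats, pts)
    dists = np.linalg.norm(images - pts[None], axis=2).min(axis=0)
    return pts[int(np.argmax(dists))]


def _choose_axes(group: IcosahedralGroup, n_chains: int) -> tuple[np.ndarray, np.ndarray]:
    """Primary and alternate 2-fold axes per chain, equatorial first.

    Near-polar axes are avoided because the azimuth φ degenerates at the
    poles, which would make angular-threshold semantics meaningless.
    """
    axes = axes_of_fold(group, FOLD_2)
    order = np.argsort(np.abs(axes[:, 2]))  # most equatorial first
    axes = axes[order]
    if 2 * n_chains > len(axes):
        raise ValueError("not enough distinct 2-fold axes for the chains")
    return axes[:n_chains], axes[n_chains:2 * n_chains]


def _make_sequences(spec: ToyFamilySpec, rng: np.random.Generator) -> list[str]:
    n = spec.residues_per_chain
    conserved_letter = {
        j: _AA1[int(rng.integers(len(_AA1)))] for j in sorted(spec.planted_seq_conserved)
    }
    seqs = []
    for _ in range(spec.n_members):
        seqs.append([
            conserved_letter.get(j + 1, _AA1[int(rng.integers(len(_AA1)))])
            for j in range(n)
        ])
    # break accidental conservation of non-planted columns
    if spec.n_members >= 2:
        for j in range(n):
            if (j + 1) in spec.planted_seq_conserved:
                continue
            column = {s[j] for s in seqs}
            if len(column) == 1:
                old = seqs[1][j]
                choices = [c for c in _AA1 if c != old]
                seqs[1][j] = choices[int(rng.integers(len(choices)))]
    return ["".join(s) for s in seqs]


def _verify_member(
    au: AsymmetricUnit,
    group: IcosahedralGroup,
    planted: frozenset[int],
    cutoff: float = 4.5,
) -> None:
    """Brute-force check: assembled contacts hit exactly the planted set."""
    assembly = assemble_capsid(au, group)
    coords, labels, numbers = [], [], []
    for si, sub in enumerate(assembly.subunits):
        for res in sub.residues:
            coords.append(res.atoms[0].coords)
            labels.append(si)
            numbers.append(res.seq_number)
    coords = np.asarray(coords)
    labels = np.asarray(labels)
    numbers = np.asarray(numbers)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    inter = pairs[labels[pairs[:, 0]] != labels[pairs[:, 1]]]
    detected = set(numbers[inter.ravel()].tolist())
    if detected != set(planted):
        raise RuntimeError(
            "infeasible toy-family spec: assembled contact set "
            f"{sorted(detected)} != planted {sorted(planted)}"
        )


def make_toy_family(
    spec: ToyFamilySpec,
    verify: bool = True,
) -> tuple[list[tuple[AsymmetricUnit, str]], ToyFamilyTruth]:
    """Build a toy capsid family with planted conservation structure.

    Returns ``(members, truth)`` where each member is an
    ``(AsymmetricUnit, aligned sequence)`` pair (member 0 is the
    reference, virus ids ``toy0, toy1, …``; the gap-free sequences align
    column *i* to residue number *i+1*) and ``truth`` carries the
    planted interface/sequence/space sets plus their intersection.
    With ``verify=True`` each member's assembled contact set is checked
    against the planted set by brute force.
    """
    rng = np.random.default_rng(spec.seed)
    group = generate_group()
    primary_axes, alternate_axes = _choose_axes(group, spec.t_number)
    safe_dir = _safe_direction(group)
    sequences = _make_sequences(spec, rng)

    planted_sorted = sorted(spec.planted_interface)
    # reference angular positions per (chain, residue): fixed tilt pattern
    ref_angles: dict[tuple[int, int], tuple[float, float]] = {}

    members: list[tuple[AsymmetricUnit, str]] = []
    for m in range(spec.n_members):
        subunits = []
        for k in range(spec.t_number):
            label = _CHAIN_LETTERS[k]
            residues = []
            safe_count = 0
            for j in range(1, spec.residues_per_chain + 1):
                if j in spec.planted_interface:
                    rank = planted_sorted.index(j)
                    tilt = 1.0 + 0.25 * (rank % 5)
                    azim = 137.5 * rank
                    if m == 0:
                        axis = primary_axes[k]
                        u = _tilted_direction(axis, tilt, azim)
                        ref_angles[(k, j)] = _angles_of(u)
                    elif j in spec.planted_space_conserved:
                        axis = primary_axes[k]
                        phi0, psi0 = ref_angles[(k, j)]
                        dphi, dpsi = rng.uniform(
                            -spec.angular_noise, spec.angular_noise, size=2
                        )
                        u = _direction_from_angles(phi0 + dphi, psi0 + dpsi)
                    else:
                        axis = alternate_axes[k]
                        u = _tilted_direction(axis, tilt, azim)
                    xyz = _contact_bead(u, axis)
                else:
                    s = safe_count
                    safe_count += 1
                    base_r = _SAFE_RADIUS + k * _CHAIN_RADIAL_GAP
                    e1, e2 = _orthonormal_frame(safe_dir)
                    ang = 2.0 * np.pi * s / _HELIX_PER_TURN
                    xyz = ((base_r + _HELIX_RISE * s) * safe_dir
                           + _HELIX_RADIUS * (np.cos(ang) * e1 + np.sin(ang) * e2))
                residues.append(Residue(
                    chain_id=label,
                    seq_number=j,
                    res_name=_AA3[sequences[m][j - 1]],
                    atoms=[Atom(serial=j, name="CA", element="C", coords=xyz)],
                ))
            subunits.append(Subunit(label=label, residues=residues))
        au = AsymmetricUnit(subunits=subunits, virus_id=f"toy{m}")
        if verify:
            _verify_member(au, group, spec.planted_interface)
        members.append((au, sequences[m]))

    chains = [_CHAIN_LETTERS[k] for k in range(spec.t_number)]
    truth = ToyFamilyTruth(
        interface_keys={(c, j, "") for c in chains for j in spec.planted_interface},
        seq_conserved_numbers=set(spec.planted_seq_conserved),
        space_conserved_keys={
            (c, j, "") for c in chains for j in spec.planted_space_conserved
        },
        hot_spot_keys={
            (c, j, "") for c in chains
            for j in spec.planted_space_conserved & spec.planted_seq_conserved
        },
    )
    return members, truth


# ---------------------------------------------------------------------------
# Exact Boltzmann umbrella sampling


@dataclass(frozen=True)
class SyntheticPotentialSpec:
    """A known 1D potential U(ξ) for validating the WHAM machinery.

    Forms (energies kcal/mol, ξ nm):

    * ``harmonic``: U = ½ ((ξ−minimum)/width)²
    * ``double_well``: U = depth·((x²−1)² − 1), x = (ξ−minimum−width)/width
      — wells at ``minimum`` and ``minimum + 2·width``, barrier ``depth``
    * ``morse_like_binding``: U = depth·((1−e^{−(ξ−minimum)/width})² − 1)
      — minimum −depth at ``minimum``, plateau → 0 at large ξ
    """

    form: str = "morse_like_binding"
    depth: float = 5.0        # kcal/mol
    minimum: float = 2.5      # nm — COM separation of the bound dimer
    width: float = 0.4        # nm
    plateau: float = 7.0      # nm (where U ≈ 0 for the binding form)
    temperature: float = 300.0
    xi_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.form not in {"harmonic", "double_well", "morse_like_binding"}:
            raise ValueError(f"unknown potential form: {self.form!r}")
        if self.width <= 0 or self.depth < 0 or self.temperature <= 0:
            raise ValueError("invalid potential parameters")

    def energy(self, xi: np.ndarray) -> np.ndarray:
        """U(ξ) in kcal/mol."""
        xi = np.asarray(xi, dtype=float)
        if self.form == "harmonic":
            return 0.5 * ((xi - self.minimum) / self.width) ** 2
        if self.form == "double_well":
            x = (xi - self.minimum - self.width) / self.width
            return self.depth * ((x * x - 1.0) ** 2 - 1.0)
        x = np.clip((xi - self.minimum) / self.width, -60.0, None)
        return self.depth * ((1.0 - np.exp(-x)) ** 2 - 1.0)

    def support(self) -> tuple[float, float]:
        if self.xi_range is not None:
            return self.xi_range
        if self.form == "double_well":
            return (self.minimum - 2.0 * self.width, self.minimum + 4.0 * self.width)
        if self.form == "morse_like_binding":
            # stop short of the repulsive wall: U(minimum − width/2) ≈ 0.4·depth
            return (max(1e-3, self.minimum - 0.5 * self.width), self.plateau)
        return (max(1e-3, self.minimum - 3.0 * self.width), self.plateau)


def sample_umbrella(
    spec: SyntheticPotentialSpec,
    windows: Sequence[BiasPotential],
    n_samples: int,
    seed: int = 0,
    grid_points: int = 10_000,
) -> list[WindowSeries]:
    """Draw window samples exactly from the biased Boltzmann densities.

    For each bias w_j the density ∝ exp(−(U+w_j)/k_BT) is tabulated on a
    ``grid_points`` grid over the potential's support and sampled by
    inverse-CDF interpolation. Deterministic under ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    lo, hi = spec.support()
    grid = np.linspace(lo, hi, grid_points)
    u_grid = spec.energy(grid)
    kT = KB_KCAL * spec.temperature
    rng = np.random.default_rng(seed)
    out: list[WindowSeries] = []
    for j, bias in enumerate(windows):
        log_p = -(u_grid + bias.energy_kcal(grid)) / kT
        log_p -= log_p.max()
        p = np.exp(log_p)
        cdf = cumulative_trapezoid(p, grid, initial=0.0)
        if (not np.isfinite(cdf[-1]) or cdf[-1] <= 0
                or np.count_nonzero(p > 1e-12) < 4):
            raise ValueError(
                f"window {j} (center {bias.center} nm): biased density "
                "underflows everywhere on the support grid"
            )
        cdf /= cdf[-1]
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        out.append(WindowSeries(
            window_id=j, center=bias.center, spring_k=bias.spring_k,
            samples=samples, temperature=spec.temperature,
        ))
    return out
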