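"""Structural data model and file I/O.

Structures are read from and written to fixed-column PDB (via gemmi),
alignments from FASTA/Clustal (via Bio.AlignIO), and umbrella-sampling
window data from a TSV metadata table plus per-window two-column text
series.

Conventions
-----------
* The capsid center is assumed to sit at the origin of the input
  coordinate frame (the VIPERdb/PDB icosahedral standard); an optional
  flag re-centers at the centroid instead.
* Alternate locations: only the highest-occupancy conformer of each atom
  is kept.
* Hydrogens are retained but flagged ``is_heavy=False``; all distance and
  surface computations downstream use heavy atoms by default.
* Window series are in nm and kJ·mol⁻¹·nm⁻² on disk; energy conversions
  (1 kcal = 4.184 kJ) happen inside the WHAM module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "Atom", "Residue", "Subunit", "AsymmetricUnit", "AlignmentSet",
    "WindowSeries", "read_structure", "write_structure", "read_alignment",
    "read_window_series", "StructureFormatError",
]

_HYDROGEN_SYMBOLS = {"H", "D", "T"}

# Alphabet used for PDB chain identifiers when writing assemblies.
_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class StructureFormatError(ValueError):
    """Raised when a structure or table file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A single atom with Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_SYMBOLS


@dataclass
class Residue:
    """A residue keyed by author numbering (chain, number, insertion code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom]
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            raise ValueError(f"residue {self.key} has no heavy atoms")
        return np.array([a.coords for a in heavy])


@dataclass
class Subunit:
    """One capsid protein chain, possibly a symmetry copy (label e.g. 'A2')."""

    label: str
    residues: list[Residue]
    source_chain: str = ""

    def __post_init__(self):
        if not self.source_chain:
            self.source_chain = self.label[:1]
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue keys in subunit {self.label}")

    def atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [
            a.coords
            for r in self.residues
            for a in (r.heavy_atoms() if heavy_only else r.atoms)
        ]
        return np.array(pts) if pts else np.empty((0, 3))

    def transformed(self, matrix: np.ndarray, label: str | None = None) -> "Subunit":
        """Return a rotated copy (rotation about the origin)."""
        R = np.asarray(matrix, dtype=float)
        new_res = [
            Residue(
                chain_id=r.chain_id,
                seq_number=r.seq_number,
                res_name=r.res_name,
                insertion_code=r.insertion_code,
                atoms=[replace(a, coords=R @ a.coords) for a in r.atoms],
            )
            for r in self.residues
        ]
        return Subunit(label=label or self.label, residues=new_res,
                       source_chain=self.source_chain)


@dataclass
class AsymmetricUnit:
    """The 1/60th of an icosahedral capsid: one subunit per chain."""

    subunits: list[Subunit]
    virus_id: str = ""

    def __post_init__(self):
        if not self.subunits:
            raise ValueError("asymmetric unit must contain at least one subunit")

    @property
    def chain_ids(self) -> list[str]:
        return [s.label for s in self.subunits]


@dataclass
class AlignmentSet:
    """A multiple sequence alignment: virus_id → aligned row."""

    sequences: dict[str, str]
    n_columns: int = 0

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        if lengths:
            n = lengths.pop()
            if self.n_columns and self.n_columns != n:
                raise ValueError("n_columns disagrees with sequence length")
            self.n_columns = n


@dataclass
class WindowSeries:
    """One umbrella-sampling window: harmonic bias metadata plus samples."""

    window_id: int
    center: float              # nm
    spring_k: float            # kJ·mol⁻¹·nm⁻²
    samples: np.ndarray        # reaction-coordinate values, nm
    temperature: float = 300.0  # K

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"window {self.window_id} has no samples")
        if self.spring_k <= 0:
            raise ValueError(f"window {self.window_id}: spring_k must be > 0")
        if self.temperature <= 0:
            raise ValueError(f"window {self.window_id}: temperature must be > 0")


# ---------------------------------------------------------------------------
# PDB I/O


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    # keep the highest-occupancy conformer of each named atom
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = [
        Atom(
            serial=a.serial,
            name=a.name,
            element=a.element.name if a.element else "X",
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=a.occ,
        )
        for a in best.values()
    ]
    if not any(a.is_heavy for a in atoms):
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        chain_id=chain_id,
        seq_number=res.seqid.num,
        res_name=res.name,
        insertion_code=icode,
        atoms=atoms,
    )


def read_structure(
    path: str | os.PathLike,
    chain_selection: Sequence[str] | None = None,
    virus_id: str = "",
    recenter: bool = False,
) -> AsymmetricUnit:
    """Read a PDB file into an :class:`AsymmetricUnit`.

    One subunit is produced per selected chain. Multi-MODEL files (the
    dialect :func:`write_structure` uses for large assemblies) yield one
    subunit per chain per model. Hydrogens are retained but flagged;
    author residue numbering is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")

    wanted = set(chain_selection) if chain_selection is not None else None
    subunits: list[Subunit] = []
    multi_model = len(st) > 1
    for mi, model in enumerate(st):
        for chain in model:
            if wanted is not None and chain.name not in wanted:
                continue
            residues = []
            for res in chain:
                conv = _convert_residue(chain.name, res)
                if conv is not None:
                    residues.append(conv)
            if not residues:
                continue
            label = f"{chain.name}{mi + 1}" if multi_model else chain.name
            subunits.append(
                Subunit(label=label, residues=residues, source_chain=chain.name)
            )
    if not subunits:
        if wanted is not None:
            raise StructureFormatError(
                f"no chains matching {sorted(wanted)} in {path}"
            )
        raise StructureFormatError(f"no usable chains in {path}")

    if recenter:
        all_xyz = np.vstack([s.atom_coords(heavy_only=False) for s in subunits])
        centroid = all_xyz.mean(axis=0)
        subunits = [
            Subunit(
                label=s.label,
                source_chain=s.source_chain,
                residues=[
                    Residue(
                        chain_id=r.chain_id,
                        seq_number=r.seq_number,
                        res_name=r.res_name,
                        insertion_code=r.insertion_code,
                        atoms=[replace(a, coords=a.coords - centroid) for a in r.atoms],
                    )
                    for r in s.residues
                ],
            )
            for s in subunits
        ]
    return AsymmetricUnit(subunits=subunits, virus_id=virus_id or path.stem)


def write_structure(subunits: Sequence[Subunit], path: str | os.PathLike) -> None:
    """Write subunits to fixed-column PDB.

    Dialect: up to 62 subunits are written as chains of a single model
    (chain ids drawn from ``A–Z a–z 0–9``). Larger assemblies — or any
    file that would exceed the 99,999 atom-serial limit in one model —
    are written as one MODEL per subunit, chain id recycling the
    subunit's source chain. :func:`read_structure` understands both.
    """
    subunits = list(subunits)
    if not subunits:
        raise ValueError("refusing to write an empty structure")
    for s in subunits:
        for r in s.residues:
            for a in r.atoms:
                if not np.all(np.isfinite(a.coords)):
                    raise ValueError(f"non-finite coordinates in {s.label}")

    n_atoms = sum(len(r.atoms) for s in subunits for r in s.residues)
    per_sub = max(sum(len(r.atoms) for r in s.residues) for s in subunits)
    if per_sub > 99999:
        raise ValueError("a single subunit exceeds the PDB atom-serial limit")
    multi_model = len(subunits) > len(_CHAIN_ALPHABET) or n_atoms > 99999

    st = gemmi.Structure()
    st.name = "capsidhs"

    def fill_chain(model: gemmi.Model, sub: Subunit, chain_id: str) -> None:
        chain = gemmi.Chain(chain_id)
        for res in sub.residues:
            g = gemmi.Residue()
            g.name = res.res_name
            g.het_flag = "A"   # force ATOM records even for bead models
            g.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for atom in res.atoms:
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.coords)
                a.occ = atom.occupancy
                g.add_atom(a)
            chain.add_residue(g)
        model.add_chain(chain)

    if multi_model:
        for i, sub in enumerate(subunits):
            model = gemmi.Model(str(i + 1))
            fill_chain(model, sub, sub.source_chain[:1] or "A")
            st.add_model(model)
    else:
        model = gemmi.Model("1")
        for i, sub in enumerate(subunits):
            fill_chain(model, sub, _CHAIN_ALPHABET[i])
        st.add_model(model)

    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# Alignment I/O


def read_alignment(path: str | os.PathLike, fmt: str = "fasta") -> AlignmentSet:
    """Read a FASTA or Clustal multiple sequence alignment.

    Sequences are upper-cased and gap characters unified to ``-``.
    """
    fmt = fmt.lower()
    if fmt not in {"fasta", "clustal"}:
        raise ValueError(f"unsupported alignment format: {fmt}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Bio.AlignIO raises on ragged rows; surface the offending file
        raise StructureFormatError(f"invalid alignment in {path}: {exc}") from exc
    sequences: dict[str, str] = {}
    for record in aln:
        seq = str(record.seq).upper().replace(".", "-")
        sequences[record.id] = seq
    return AlignmentSet(sequences=sequences)


# ---------------------------------------------------------------------------
# Umbrella window I/O

_META_COLUMNS = ("window_id", "center_nm", "spring_k_kJ_mol_nm2")


def read_window_series(
    metadata_path: str | os.PathLike,
    series_dir: str | os.PathLike,
    temperature: float = 300.0,
) -> list[WindowSeries]:
    """Read umbrella windows from a TSV metadata table plus series files.

    The metadata table needs columns ``window_id``, ``center_nm`` and
    ``spring_k_kJ_mol_nm2`` (optionally ``series_file``). Each series
    file is a two-column (time, ξ) text table; lines starting with ``#``
    or ``@`` are ignored, matching the common pull-output dialect.
    """
    meta = pd.read_csv(metadata_path, sep="\t")
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise StructureFormatError(
            f"metadata table missing column(s): {', '.join(missing_cols)}"
        )
    series_dir = Path(series_dir)
    missing_ids: list[int] = []
    paths: list[Path] = []
    for _, row in meta.iterrows():
        wid = int(row["window_id"])
        if "series_file" in meta.columns and isinstance(row.get("series_file"), str):
            p = series_dir / row["series_file"]
        else:
            p = series_dir / f"window_{wid}.dat"
        if not p.exists():
            missing_ids.append(wid)
        paths.append(p)
    if missing_ids:
        raise FileNotFoundError(
            f"no series file for window id(s): {missing_ids}"
        )

    windows: list[WindowSeries] = []
    for (_, row), p in zip(meta.iterrows(), paths):
        data = np.loadtxt(p, comments=("#", "@"), ndmin=2)
        if data.shape[1] < 2:
            raise StructureFormatError(
                f"{p}: expected two columns (time, xi), got {data.shape[1]}"
            )
        temp = float(row["temperature_K"]) if "temperature_K" in meta.columns else temperature
        windows.append(
            WindowSeries(
                window_id=int(row["window_id"]),
                center=float(row["center_nm"]),
                spring_k=float(row["spring_k_kJ_mol_nm2"]),
                samples=data[:, 1],
                temperature=temp,
            )
        )
    return windows


def write_window_series(
    windows: Iterable[WindowSeries],
    metadata_path: str | os.PathLike,
    series_dir: str | os.PathLike,
    dt: float = 1.0,
) -> None:
    """Write windows in the format :func:`read_window_series` reads."""
    series_dir = Path(series_dir)
    series_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in windows:
        rows.append(
            {"window_id": w.window_id, "center_nm": w.center,
             "spring_k_kJ_mol_nm2": w.spring_k, "temperature_K": w.temperature}
        )
        t = np.arange(len(w.samples)) * dt
        out = np.column_stack([t, w.samples])
        np.savetxt(
            series_dir / f"window_{w.window_id}.dat", out,
            header="time_ps xi_nm", fmt="%.6f",
        )
    Path(metadata_path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)
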