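"""End-to-end orchestration of the hot-spot prediction pipeline.

Given one asymmetric unit per family member plus a multiple sequence
alignment, run: assembly → interface detection → CapsidMap projection →
MSA conservation → angular-map alignment → three-way intersection.
The CLI, the test suite and the acceptance script all call this single
entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from capsidhs.capsidmap import (
    CapsidMap,
    ConservationConfig,
    HotSpotResult,
    align_maps,
    build_capsidmap,
    column_residue_maps,
    conserved_columns,
    predict_hotspots,
)
from capsidhs.interfaces import (
    ContactCriterion,
    InterfacePair,
    find_interfaces,
    interface_residue_union,
)
from capsidhs.structures import AlignmentSet, AsymmetricUnit
from capsidhs.symmetry import IcosahedralGroup, assemble_capsid, generate_group

__all__ = ["FamilyPrediction", "predict_family"]


@dataclass
class FamilyPrediction:
    """Everything the pipeline computed, keyed by virus."""

    result: HotSpotResult
    maps: dict[str, CapsidMap]
    interfaces: dict[str, list[InterfacePair]]


def _fold_annotation(pairs: Sequence[InterfacePair]) -> dict:
    """Fold class per asymmetric-unit residue key, preferring 2-fold.

    A residue can appear in interfaces of several folds (e.g. around
    both a 2-fold and a quasi contact); the annotation lists all folds
    seen, joined with '/', with strict folds ordered before 'quasi'.
    """
    seen: dict[tuple[str, int, str], set[str]] = {}
    for p in pairs:
        if p.fold_class is None:
            continue
        for rc in list(p.residues_i) + list(p.residues_j):
            cls = rc.key[0].rstrip("0123456789")
            seen.setdefault((cls, rc.key[1], rc.key[2]), set()).add(p.fold_class)
    order = {"2-fold": 0, "3-fold": 1, "5-fold": 2, "quasi": 3}
    return {
        k: "/".join(sorted(v, key=lambda f: order.get(f, 9)))
        for k, v in seen.items()
    }


def predict_family(
    members: Mapping[str, AsymmetricUnit],
    alignment: AlignmentSet,
    reference: str | None = None,
    criterion: ContactCriterion = ContactCriterion(),
    conservation: ConservationConfig = ConservationConfig(),
    numbering_offsets: Mapping[str, int] | None = None,
    group: IcosahedralGroup | None = None,
) -> FamilyPrediction:
    """Run the full conservation pipeline on a virus family.

    ``members`` maps virus id → asymmetric unit in the standard
    icosahedral orientation; every virus id must appear in the
    alignment. At least two members are required — a single structure
    cannot show quaternary-position conservation.
    """
    if len(members) < 2:
        raise ValueError(
            "hot-spot prediction needs at least two family members "
            "(structure and sequence); got "
            f"{len(members)}"
        )
    missing = [v for v in members if v not in alignment.sequences]
    if missing:
        raise KeyError(f"viruses missing from the alignment: {missing}")
    reference = reference or next(iter(members))
    group = group or generate_group()

    interfaces: dict[str, list[InterfacePair]] = {}
    iface_sets: dict[str, set] = {}
    maps: dict[str, CapsidMap] = {}
    for virus, au in members.items():
        assembly = assemble_capsid(au, group)
        pairs = find_interfaces(assembly, criterion)
        interfaces[virus] = pairs
        iface_sets[virus] = interface_residue_union(pairs)
        maps[virus] = build_capsidmap(au, iface_sets[virus], conservation)

    corr = column_residue_maps(alignment, numbering_offsets)
    _, seq_sets = conserved_columns(alignment, numbering_offsets)
    space_sets = align_maps(
        [maps[v] for v in members], corr, conservation, reference=reference
    )
    result = predict_hotspots(
        iface_sets, seq_sets, space_sets,
        reference=reference,
        fold_annotation=_fold_annotation(interfaces[reference]),
    )
    return FamilyPrediction(result=result, maps=maps, interfaces=interfaces)
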