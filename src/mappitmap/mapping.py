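"""Mapping relative MAPPIT signals onto a protein structure.

The per-substitution relative signals are reduced to one value per residue
(minimum by default — the question being whether the residue *can* matter),
written as an attribute list in the residue-attribute text dialect understood
by UCSF Chimera's "define attribute" tool, binned against up to three
user-chosen thresholds with linear colour-intensity interpolation, and
clustered into spatial patches: connected components of interaction-affecting
residues in a heavy-atom contact graph.  Isolated residues or very small
patches are flagged, since such hits are as likely to reflect fold or
stability effects as a genuine binding surface; credible interfaces present
as patches of multiple adjacent residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .library import ReferenceConstruct

ADJACENCY_CUTOFF = 5.0  # Å, minimum heavy-atom distance for residue contact
MIN_PATCH_SIZE = 3


class MappingError(ValueError):
    """Structure-mapping errors."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity plus its heavy-atom coordinates (Å)."""

    chain: str
    number: int
    name: str
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] < 1:
            raise MappingError(
                f"residue {self.chain}:{self.number} has no heavy atoms"
            )
        object.__setattr__(self, "coords", coords)


@dataclass
class StructureModel:
    """A minimal structure: an ordered list of residues with coordinates."""

    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            key = (r.chain, r.number)
            if key in seen:
                raise MappingError(f"duplicate residue {key}")
            seen.add(key)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    @classmethod
    def from_pdb(cls, path, chain: str | None = None) -> "StructureModel":
        """Read a PDB file (first model; hydrogens and waters skipped)."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", str(path))
        model = next(structure.get_models())
        residues = []
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                hetflag, resseq, _icode = res.id
                if hetflag != " ":  # skip HETATM/water
                    continue
                coords = np.array(
                    [a.coord for a in res if a.element != "H"], dtype=float
                )
                if coords.size == 0:
                    continue
                residues.append(
                    ResidueRecord(
                        chain=ch.id, number=resseq, name=res.resname, coords=coords
                    )
                )
        if not residues:
            raise MappingError(f"no residues parsed from {path}")
        return cls(residues=residues)


def structure_to_pdb(structure: StructureModel) -> str:
    """Serialise a StructureModel as minimal PDB ATOM records.

    Atoms of each residue are written as CA, CB, ... in order; only the first
    two atoms get those canonical names, further atoms are numbered carbons.
    """
    lines = []
    serial = 1
    atom_names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    for res in structure.residues:
        for i, xyz in enumerate(res.coords):
            name = atom_names[i] if i < len(atom_names) else f"C{i}"
            name_field = f" {name:<3s}" if len(name) <= 3 else name[:4]
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res.name:>3s} "
                f"{res.chain:1s}{res.number:4d}"
                f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue attributes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueAttribute:
    """A named numeric attribute over residues (full-protein numbering)."""

    name: str
    values: Mapping[int, float]

    def __post_init__(self) -> None:
        if any(ch.isspace() for ch in self.name):
            raise MappingError("attribute name must not contain whitespace")


def build_attribute(
    substitution_signals: Iterable[tuple[int, float]],
    ref: ReferenceConstruct,
    name: str = "relMappit",
    reduce: str = "min",
    structure: StructureModel | None = None,
) -> tuple[ResidueAttribute, list[int]]:
    """Reduce per-substitution relative signals to one value per residue.

    Parameters
    ----------
    substitution_signals
        ``(codon_index, relative_signal)`` pairs in construct numbering.
    reduce
        ``"min"`` (default; keeps the most disruptive substitution) or
        ``"mean"``.
    structure
        When given, residues that fall outside the structure are reported in
        the second return value rather than silently dropped.

    Non-mutated residues are simply absent from the attribute map (rendered
    grey / non-mutated downstream).
    """
    if reduce not in ("min", "mean"):
        raise MappingError(f"unknown reduction {reduce!r}")
    per_residue: dict[int, list[float]] = {}
    for codon_index, value in substitution_signals:
        resnum = ref.residue_number(codon_index)
        per_residue.setdefault(resnum, []).append(float(value))
    reducer = min if reduce == "min" else (lambda v: float(np.mean(v)))
    values = {r: float(reducer(v)) for r, v in sorted(per_residue.items())}
    unmapped: list[int] = []
    if structure is not None:
        present = set(structure.residue_numbers)
        unmapped = sorted(r for r in values if r not in present)
    return ResidueAttribute(name=name, values=values), unmapped


def write_attribute_file(attr: ResidueAttribute, path=None) -> str:
    """Serialise an attribute in the residue-attribute text dialect.

    Three header lines followed by one tab-indented line per residue in
    ascending residue order; values are rendered with 6 significant digits::

        attribute: relMappit
        match mode: 1-to-1
        recipient: residues
        \t:163\t0.37
    """
    if not attr.values:
        raise MappingError("cannot write an empty attribute map")
    out = io.StringIO()
    out.write(f"attribute: {attr.name}\n")
    out.write("match mode: 1-to-1\n")
    out.write("recipient: residues\n")
    for resnum in sorted(attr.values):
        out.write(f"\t:{resnum}\t{attr.values[resnum]:.6g}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_attribute_file(text: str) -> ResidueAttribute:
    """Inverse of :func:`write_attribute_file`."""
    name = None
    values: dict[int, float] = {}
    for line in text.splitlines():
        if line.startswith("attribute:"):
            name = line.split(":", 1)[1].strip()
        elif line.startswith("\t:"):
            resfield, valfield = line.lstrip("\t")[1:].split("\t")
            values[int(resfield)] = float(valfield)
    if name is None:
        raise MappingError("not an attribute file: missing 'attribute:' header")
    return ResidueAttribute(name=name, values=values)


# ---------------------------------------------------------------------------
# Threshold binning with colour intensity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorScheme:
    """1-3 ascending thresholds; one colour per band (len(thresholds)+1 bands,
    the last band collecting values above every threshold)."""

    thresholds: tuple[float, ...]
    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.thresholds) <= 3:
            raise MappingError("scheme needs 1-3 thresholds")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise MappingError("thresholds must be strictly ascending")
        if len(self.colors) != len(self.thresholds) + 1:
            raise MappingError(
                "need one colour per band (len(thresholds) + 1 colours)"
            )


@dataclass(frozen=True)
class BandAssignment:
    band: int
    color: str
    intensity: float  # in [0, 1]


def bin_and_color(
    attr: ResidueAttribute, scheme: ColorScheme
) -> dict[int, BandAssignment]:
    """Assign each residue a threshold band and a colour intensity.

    Band = index of the first threshold >= value (the last band for values
    above every threshold).  Intensity interpolates the value's position
    between its flanking thresholds linearly (lower flank 0 for the first
    band; 1.0 for the open last band), clamped to [0, 1] — a value equal to a
    threshold has intensity 1 for that threshold's colour.
    """
    thresholds = scheme.thresholds
    k = len(thresholds)
    out: dict[int, BandAssignment] = {}
    for resnum, value in attr.values.items():
        band = k  # open last band unless a threshold catches the value
        for i, t in enumerate(thresholds):
            if value <= t:
                band = i
                break
        if band == k:
            intensity = 1.0
        else:
            lo = thresholds[band - 1] if band > 0 else 0.0
            hi = thresholds[band]
            intensity = 1.0 if hi == lo else (value - lo) / (hi - lo)
        out[resnum] = BandAssignment(
            band=band,
            color=scheme.colors[band],
            intensity=float(min(1.0, max(0.0, intensity))),
        )
    return out


# ---------------------------------------------------------------------------
# Contact graph and interface patches
# ---------------------------------------------------------------------------

def residue_adjacency(
    structure: StructureModel, cutoff: float = ADJACENCY_CUTOFF
) -> nx.Graph:
    """Residue contact graph: an undirected edge joins two residues whose
    minimum heavy-atom distance is <= ``cutoff`` Å.

    Nodes are residue numbers; the structure must not reuse a residue number
    across chains (restrict with ``StructureModel.from_pdb(chain=...)`` if it
    does).
    """
    if cutoff <= 0:
        raise MappingError("cutoff must be positive")
    if not structure.residues:
        raise MappingError("empty structure")
    numbers = structure.residue_numbers
    if len(set(numbers)) != len(numbers):
        raise MappingError(
            "residue numbers are not unique across chains; select one chain"
        )
    coords = np.vstack([r.coords for r in structure.residues])
    owner = np.concatenate(
        [np.full(len(r.coords), i) for i, r in enumerate(structure.residues)]
    )
    graph = nx.Graph()
    graph.add_nodes_from(numbers)
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(cutoff):
        ra, rb = owner[a], owner[b]
        if ra != rb:
            graph.add_edge(numbers[ra], numbers[rb])
    return graph


@dataclass(frozen=True)
class InterfacePatch:
    """A connected cluster of interaction-affecting residues."""

    residue_numbers: frozenset[int]
    isolated: bool

    @property
    def size(self) -> int:
        return len(self.residue_numbers)


def detect_patches(
    affected: Iterable[int],
    adjacency: nx.Graph,
    min_patch_size: int = MIN_PATCH_SIZE,
) -> list[InterfacePatch]:
    """Connected components of the affected residues in the contact graph.

    Components smaller than ``min_patch_size`` are flagged ``isolated`` — to
    be interpreted with caution (possible stability/folding artefacts rather
    than interface).  Affected residues missing from the graph become
    singleton patches.  Patches are returned largest first and partition the
    affected set.
    """
    affected_set = set(int(r) for r in affected)
    in_graph = affected_set & set(adjacency.nodes)
    sub = adjacency.subgraph(in_graph)
    components = [set(c) for c in nx.connected_components(sub)]
    components.extend({r} for r in sorted(affected_set - in_graph))
    patches = [
        InterfacePatch(
            residue_numbers=frozenset(c), isolated=len(c) < min_patch_size
        )
        for c in components
    ]
    patches.sort(key=lambda p: (-p.size, min(p.residue_numbers)))
    return patches


def patches_to_frame(patches: Sequence[InterfacePatch]) -> pd.DataFrame:
    """Patch report; the stability-prediction column is left for externally
    supplied annotations (e.g. fold-stability estimates) and never filtered on."""
    rows = []
    for i, p in enumerate(patches, start=1):
        rows.append(
            {
                "patch_id": i,
                "size": p.size,
                "isolated": int(p.isolated),
                "residues": ";".join(str(r) for r in sorted(p.residue_numbers)),
                "stability_annotation": "",
            }
        )
    return pd.DataFrame(rows)
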