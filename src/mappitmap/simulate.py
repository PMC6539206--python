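"""Synthetic mutant libraries, screens and structures with known ground truth.

The generator stands in for the wet-lab steps so the whole analysis chain is
exercisable end to end: error-prone-PCR clone sequences drawn from a
controllable per-base mutation rate and 12-way substitution spectrum;
stimulated/unstimulated luciferase counts with multiplicative log-normal well
noise, per-plate multiplicative effects and configurable per-residue
interaction effects; and an ideal α-helix toy structure for the mapping stage.

Multiplicative (log-normal) noise and per-plate factors are chosen
deliberately: the plate-median normalization of the analysis is built to
cancel exactly such effects, so the generator makes that cancellation
testable.  Negative-control preys are modelled as non-interacting — their
stimulated wells stay at baseline.

Everything is driven by an integer-seeded NumPy generator; identical seeds
give identical libraries, layouts and readouts on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, sin
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import (
    ClassifiedClone,
    CloneClass,
    CloneRecord,
    NUCLEOTIDES,
    ReferenceConstruct,
    classify_library,
    translate_cds,
)
from .mapping import ResidueRecord, StructureModel, structure_to_pdb
from .plates import DnaPlate96, ROWS_96, COLS_96, TransfectionPlate384, WellKind, expand_to_transfection, well_name


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpectrum:
    """Per-base mutation probability plus the 12 ordered substitution rates.

    ``rates`` maps ``"A>C"``-style keys to non-negative weights; they are
    normalized internally.  The error-prone-PCR default of 0.0045
    substitutions per base (4.5/kb) puts a ~180 nt insert in the regime where
    roughly a third of clones carry a single missense change.
    """

    per_base_rate: float = 0.0045
    rates: Mapping[str, float] = field(
        default_factory=lambda: {
            f"{a}>{b}": 1.0 for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b
        }
    )

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_rate < 1:
            raise SimulationError("per_base_rate must be in [0, 1)")
        expected = {f"{a}>{b}" for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b}
        if set(self.rates) != expected:
            raise SimulationError("spectrum must define all 12 substitution types")
        if any(v < 0 for v in self.rates.values()) or sum(self.rates.values()) <= 0:
            raise SimulationError("spectrum rates must be non-negative, not all zero")

    def normalized(self) -> dict[str, float]:
        total = sum(self.rates.values())
        return {k: v / total for k, v in self.rates.items()}

    def alt_distribution(self, base: str) -> tuple[list[str], list[float]]:
        """Conditional distribution of the alternate base given the reference
        base mutates."""
        alts = [b for b in NUCLEOTIDES if b != base]
        weights = np.array([self.rates[f"{base}>{b}"] for b in alts], dtype=float)
        if weights.sum() == 0:
            weights = np.ones(3)
        return alts, list(weights / weights.sum())


@dataclass(frozen=True)
class NoiseModel:
    """Readout model for the luciferase counts.

    Stimulated wells: baseline × fold_induction × effect(prey) × plate × well;
    unstimulated wells: baseline × plate × well; ``plate`` and ``well`` are
    log-normal with the given sigmas (of the underlying normal).  All counts
    are in counts per second.
    """

    baseline: float = 2000.0
    fold_induction: float = 25.0
    sigma_well: float = 0.10
    sigma_plate: float = 0.15

    def __post_init__(self) -> None:
        if min(self.baseline, self.fold_induction) <= 0:
            raise SimulationError("baseline and fold_induction must be positive")
        if min(self.sigma_well, self.sigma_plate) < 0:
            raise SimulationError("noise sigmas must be non-negative")


def random_reference(
    n_codons: int, seed: int | np.random.Generator, construct_id: str = "construct", residue_offset: int = 1
) -> ReferenceConstruct:
    """A random stop-free CDS of ``n_codons`` codons starting with ATG."""
    rng = np.random.default_rng(seed)
    sense = [
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if translate_cds(a + b + c) != "*"
    ]
    codons = ["ATG"] + [
        sense[i] for i in rng.integers(0, len(sense), size=n_codons - 1)
    ]
    return ReferenceConstruct(
        construct_id=construct_id, cds="".join(codons), residue_offset=residue_offset
    )


def simulate_clone_sequences(
    ref: ReferenceConstruct,
    n_clones: int,
    spectrum: MutationSpectrum | None = None,
    seed: int | np.random.Generator = 0,
    pcr_condition: str = "epPCR",
    plate_prefix: str = "LIB",
) -> tuple[list[CloneRecord], dict[str, list[tuple[int, str, str]]]]:
    """Draw error-prone-PCR clones: every base mutates independently with the
    per-base probability; the alternate base follows the spectrum.

    Returns the clones plus the generating truth: clone_id -> list of
    ``(nt_pos, ref_base, alt_base)`` substitutions actually applied.  Clone
    IDs carry ``plate_well`` provenance over consecutive 96-well colony
    plates.
    """
    spectrum = spectrum or MutationSpectrum()
    rng = np.random.default_rng(seed)
    wells = [well_name(r, c) for r in ROWS_96 for c in COLS_96]
    clones: list[CloneRecord] = []
    truth: dict[str, list[tuple[int, str, str]]] = {}
    for i in range(n_clones):
        plate = i // 96 + 1
        well = wells[i % 96]
        clone_id = f"{plate_prefix}{plate:02d}_{well}"
        bases = list(ref.cds)
        subs: list[tuple[int, str, str]] = []
        hits = np.nonzero(rng.random(len(bases)) < spectrum.per_base_rate)[0]
        for pos in hits:
            ref_base = bases[pos]
            alts, probs = spectrum.alt_distribution(ref_base)
            alt = alts[rng.choice(3, p=probs)]
            bases[pos] = alt
            subs.append((int(pos) + 1, ref_base, alt))
        clones.append(
            CloneRecord(
                clone_id=clone_id,
                sequence="".join(bases),
                source_well=clone_id,
                pcr_condition=pcr_condition,
            )
        )
        truth[clone_id] = subs
    return clones, truth


def simulate_screen(
    plates: Sequence[TransfectionPlate384],
    effect_map: Mapping[str, float],
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate luciferase readings for every non-empty well of the layouts.

    ``effect_map`` gives the true interaction-effect multiplier per mutant
    clone (1.0 = wildtype-like).  Wildtype preys have effect 1; negative
    controls have effect 1/fold_induction, i.e. no interaction-driven
    induction.  Missing mutant effects are an error.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    rows = []
    for plate in plates:
        plate_effect = float(np.exp(rng.normal(0.0, noise.sigma_plate))) if noise.sigma_plate else 1.0
        for well in sorted(plate.wells):
            assignment = plate.wells[well]
            mixture = plate.mixtures[assignment.mixture_id]
            if mixture.kind is WellKind.WILDTYPE:
                effect = 1.0
            elif mixture.kind is WellKind.NEGATIVE_CONTROL:
                effect = 1.0 / noise.fold_induction
            else:
                if mixture.prey_id not in effect_map:
                    raise SimulationError(
                        f"no effect entry for mutant prey {mixture.prey_id}"
                    )
                effect = float(effect_map[mixture.prey_id])
            well_noise = float(np.exp(rng.normal(0.0, noise.sigma_well))) if noise.sigma_well else 1.0
            counts = noise.baseline * plate_effect * well_noise
            if assignment.stimulated:
                counts *= noise.fold_induction * effect
            rows.append(
                {"plate_id": plate.plate_id, "well": well, "counts": counts}
            )
    return pd.DataFrame(rows)


def make_toy_structure(
    n_residues: int, chain: str = "A", first_residue: int = 1
) -> tuple[StructureModel, str]:
    """An ideal α-helix Cα+Cβ trace: 1.5 Å rise and 100° twist per residue,
    Cα radius 2.3 Å (Cβ 1.5 Å further out).  Returns the model and its PDB
    text.  Consecutive residues sit ~3.8 Å apart, inside the default 5 Å
    contact cutoff."""
    if n_residues < 2:
        raise SimulationError("a toy helix needs at least 2 residues")
    residues = []
    for i in range(n_residues):
        theta = i * 100.0 * pi / 180.0
        z = 1.5 * i
        ca = (2.3 * cos(theta), 2.3 * sin(theta), z)
        cb = (3.8 * cos(theta), 3.8 * sin(theta), z + 0.5)
        residues.append(
            ResidueRecord(
                chain=chain,
                number=first_residue + i,
                name="ALA",
                coords=np.array([ca, cb]),
            )
        )
    model = StructureModel(residues=residues)
    return model, structure_to_pdb(model)


# ---------------------------------------------------------------------------
# End-to-end synthetic study
# ---------------------------------------------------------------------------

def write_synthetic_screen(sim: "SyntheticScreen", out_dir) -> dict[str, "Path"]:
    """Persist a synthetic screen as the same file formats the pipeline
    consumes (FASTA reference and clones, CSV DNA plates/layout/readings,
    PDB structure, plus the ground-truth effect map)."""
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .library import write_clones_fasta
    from .plates import dna_plate_to_frame, layout_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference_fasta"] = out / "reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(sim.reference.cds), id=sim.reference.construct_id, description="")],
        str(paths["reference_fasta"]),
        "fasta",
    )
    paths["clones_fasta"] = out / "clones.fasta"
    write_clones_fasta(sim.clones, paths["clones_fasta"])
    paths["dna_plates_csv"] = out / "dna_plates.csv"
    pd.concat([dna_plate_to_frame(p) for p in sim.dna_plates]).to_csv(
        paths["dna_plates_csv"], index=False, float_format="%.6g"
    )
    paths["layout_csv"] = out / "layout.csv"
    layout_to_frame(sim.plates).to_csv(
        paths["layout_csv"], index=False, float_format="%.6g"
    )
    paths["readings_csv"] = out / "readings.csv"
    sim.readings.to_csv(paths["readings_csv"], index=False, float_format="%.6g")
    paths["structure_pdb"] = out / "structure.pdb"
    paths["structure_pdb"].write_text(sim.pdb_text)
    paths["truth_csv"] = out / "true_effects.csv"
    pd.DataFrame(
        [
            {"clone_id": k, "effect": v}
            for k, v in sorted(sim.effect_map.items())
        ]
    ).to_csv(paths["truth_csv"], index=False, float_format="%.6g")
    return paths


@dataclass
class SyntheticScreen:
    """A complete simulated study: library, layouts, readings and truth."""

    reference: ReferenceConstruct
    clones: list[CloneRecord]
    truth: dict[str, list[tuple[int, str, str]]]
    classified: list[ClassifiedClone]
    dna_plates: list[DnaPlate96]
    plates: list[TransfectionPlate384]
    readings: pd.DataFrame
    effect_map: dict[str, float]
    interface_codons: tuple[int, ...]
    structure: StructureModel
    pdb_text: str
    noise: NoiseModel
    bait_id: str

    @property
    def interface_residues(self) -> tuple[int, ...]:
        """Planted interface in full-protein numbering."""
        return tuple(self.reference.residue_number(c) for c in self.interface_codons)


def simulate_synthetic_screen(
    seed: int,
    n_codons: int = 60,
    residue_offset: int = 159,
    n_clones: int = 480,
    n_dna_plates: int = 2,
    interface_codons: Sequence[int] = tuple(range(20, 28)),
    interface_effect: float = 0.2,
    n_experiments: int = 3,
    spectrum: MutationSpectrum | None = None,
    noise: NoiseModel | None = None,
    bait_id: str = "bait",
) -> SyntheticScreen:
    """Generate a full synthetic screen with planted interface residues.

    The defaults emulate a compact screening campaign: a 60-codon prey domain
    (numbered from residue 159 of the full-length protein), 480 sequenced
    clones at 4.5 substitutions/kb, the single-missense clones consolidated
    onto up to two 96-well DNA plates, three replicate transfection
    experiments, a 25-fold wildtype induction with σ=0.10 well noise and
    σ=0.15 plate effects, and a contiguous 8-residue interface whose mutants
    drop the interaction signal to 0.2× wildtype.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    # independent child seeds so each stage is individually reproducible
    seeds = rng.integers(0, 2**31 - 1, size=4)

    reference = random_reference(
        n_codons, int(seeds[0]), construct_id="prey-domain", residue_offset=residue_offset
    )
    clones, truth = simulate_clone_sequences(
        reference, n_clones, spectrum, int(seeds[1])
    )
    classified = classify_library(clones, reference)
    single = [
        c for c in classified if c.classification is CloneClass.SINGLE_MISSENSE
    ]

    interface = set(interface_codons)
    if max(interface) > reference.n_codons:
        raise SimulationError("interface codons fall outside the construct")
    effect_map: dict[str, float] = {}
    for c in single:
        codon, _ref_aa, _alt_aa = c.missense_substitution
        effect_map[c.clone.clone_id] = (
            interface_effect if codon in interface else 1.0
        )

    od_rng = np.random.default_rng(int(seeds[2]))
    dna_plates: list[DnaPlate96] = []
    capacity = 72
    for p in range(n_dna_plates):
        batch = [c.clone.clone_id for c in single[p * capacity : (p + 1) * capacity]]
        if not batch:
            break
        plate_id = f"DNA{p + 1:02d}"
        od = {}
        conc = {}
        for r in ROWS_96:
            for col in COLS_96:
                w = well_name(r, col)
                od[w] = float(od_rng.normal(1.95, 0.04))
                conc[w] = float(od_rng.normal(75.0, 10.0))
        dna_plates.append(
            DnaPlate96.from_clone_ids(
                plate_id, batch, dna_conc=conc, od_ratio=od
            )
        )
    if not dna_plates:
        raise SimulationError("no single-missense clones to plate")

    plates: list[TransfectionPlate384] = []
    for e in range(1, n_experiments + 1):
        for dp in dna_plates:
            a, b = expand_to_transfection(dp, bait_id, experiment_id=f"E{e}")
            plates.extend([a, b])

    readings = simulate_screen(plates, effect_map, noise, int(seeds[3]))
    structure, pdb_text = make_toy_structure(
        n_codons, first_residue=residue_offset
    )
    return SyntheticScreen(
        reference=reference,
        clones=clones,
        truth=truth,
        classified=classified,
        dna_plates=dna_plates,
        plates=plates,
        readings=readings,
        effect_map=effect_map,
        interface_codons=tuple(sorted(interface)),
        structure=structure,
        pdb_text=pdb_text,
        noise=noise,
        bait_id=bait_id,
    )
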