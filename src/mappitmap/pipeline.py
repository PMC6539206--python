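"""File-driven orchestration of the full interface-mapping workflow.

Stages communicate only via files (FASTA, CSV, PDB, the attribute dialect),
so any stage can be rerun in isolation and every number in the final report
is recomputable from the persisted intermediate tables.  A run is fully
deterministic given its inputs: rerunning the pipeline on the same files
produces byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .library import (
    CloneClass,
    ReferenceConstruct,
    classify_library,
    read_clones_fasta,
    read_reference_fasta,
    select_pcr_condition,
    spectrum_to_frame,
    summaries_to_frame,
    summarize_by_condition,
)
from .mapping import (
    ADJACENCY_CUTOFF,
    MIN_PATCH_SIZE,
    StructureModel,
    build_attribute,
    detect_patches,
    patches_to_frame,
    residue_adjacency,
    write_attribute_file,
)
from .plates import frame_to_dna_plates, frame_to_layout, layout_to_frame, qc_dna, expand_to_transfection
from .signals import (
    FOLD_INDUCTION_MIN,
    MIN_WELLS_PER_ARM,
    MIN_WILDTYPES_PER_PLATE,
    MutantCall,
    analyze_screen,
    plot_signal_histograms,
)

logger = logging.getLogger("mappitmap")

FLOAT_FORMAT = "%.6g"  # fixed CSV float rendering keeps reruns byte-identical


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    reference_fasta: Path
    clones_fasta: Path
    layout_csv: Path
    readings_csv: Path
    structure_pdb: Path
    out_dir: Path
    bait_id: str = "bait"
    residue_offset: int = 1
    adjacency_cutoff: float = ADJACENCY_CUTOFF
    min_patch_size: int = MIN_PATCH_SIZE
    min_wells_per_arm: int = MIN_WELLS_PER_ARM
    min_wildtypes: int = MIN_WILDTYPES_PER_PLATE
    fold_induction_min: float = FOLD_INDUCTION_MIN
    attribute_name: str = "relMappit"
    residue_reduce: str = "min"
    cutoff_lower: float | None = None  # overrides the wildtype-derived cut-offs
    cutoff_upper: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        paths = {
            k: Path(raw[k])
            for k in (
                "reference_fasta",
                "clones_fasta",
                "layout_csv",
                "readings_csv",
                "structure_pdb",
                "out_dir",
            )
        }
        extra = {k: v for k, v in raw.items() if k not in paths}
        return cls(**paths, **extra)

    def validate(self) -> None:
        for name in (
            "reference_fasta",
            "clones_fasta",
            "layout_csv",
            "readings_csv",
            "structure_pdb",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.residue_reduce not in ("min", "mean"):
            raise ValueError("residue_reduce must be 'min' or 'mean'")
        if self.min_patch_size < 1:
            raise ValueError("min_patch_size must be >= 1")
        if self.adjacency_cutoff <= 0:
            raise ValueError("adjacency_cutoff must be positive")
        if (self.cutoff_lower is None) != (self.cutoff_upper is None):
            raise ValueError("cut-off overrides must be given as a pair")


def setup_logging(log_file: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when given, to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file, mode="w"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunReport:
    """Paths of every artefact written by :func:`run_full_pipeline`."""

    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Run library classification, signal analysis and structure mapping.

    QC failures (excluded mixtures, dropped plates, unmapped residues) are
    logged and recorded; downstream stages continue on the surviving data and
    the run only aborts if nothing survives.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)
    setup_logging(out / "run.log")
    logger.info("mappitmap %s | seed %d", __version__, config.seed)

    def save(key: str, frame: pd.DataFrame) -> None:
        path = out / f"{key}.csv"
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        report.files[key] = path

    # --- stage 1: mutant library -----------------------------------------
    ref = read_reference_fasta(config.reference_fasta, config.residue_offset)
    clones = read_clones_fasta(config.clones_fasta)
    classified = classify_library(clones, ref)
    summaries = summarize_by_condition(classified, ref)
    save("library_summary", summaries_to_frame(summaries))
    save("mutation_spectrum", spectrum_to_frame(summaries))
    best = select_pcr_condition(summaries)
    logger.info(
        "library: %d clones, best PCR condition %r (%d single missense)",
        len(classified),
        best,
        summaries[best].class_counts.get(CloneClass.SINGLE_MISSENSE.value, 0),
    )
    substitution_map = {
        c.clone.clone_id: c.substitution_label(ref)
        for c in classified
        if c.classification is CloneClass.SINGLE_MISSENSE
    }
    codon_of_sub = {
        c.substitution_label(ref): c.missense_substitution[0]
        for c in classified
        if c.classification is CloneClass.SINGLE_MISSENSE
    }

    # --- stage 2: layout ---------------------------------------------------
    layout_frame = pd.read_csv(config.layout_csv)
    plates = frame_to_layout(layout_frame)
    save("layout", layout_to_frame(plates))
    logger.info("layout: %d transfection plates", len(plates))

    # --- stage 3: signals --------------------------------------------------
    readings = pd.read_csv(config.readings_csv)
    result = analyze_screen(
        plates,
        readings,
        substitution_map=substitution_map,
        min_wells_per_arm=config.min_wells_per_arm,
        min_wildtypes=config.min_wildtypes,
        fold_induction_min=config.fold_induction_min,
    )
    cutoffs = result.cutoffs
    if config.cutoff_lower is not None:
        from .signals import CutoffPair, classify_mutants, classify_relative

        cutoffs = CutoffPair(config.cutoff_lower, config.cutoff_upper)
        result.cutoffs = cutoffs
        result.calls = classify_mutants(result.relatives, cutoffs)
        if result.per_substitution is not None:
            result.per_substitution["call"] = [
                classify_relative(v, cutoffs).value
                for v in result.per_substitution["relative_signal"]
            ]
        logger.info("using cut-off overrides (%.4g, %.4g)", cutoffs.lower, cutoffs.upper)
    for line in result.qc_log:
        logger.warning("QC: %s", line)
    save("mixture_signals", result.mixture_signals)
    save("relative_signals", result.relatives_frame())
    if result.per_substitution is not None:
        save("substitution_signals", result.per_substitution)
    save(
        "cutoffs",
        pd.DataFrame(
            [{"lower": cutoffs.lower, "upper": cutoffs.upper}]
        ),
    )
    nc = result.negative_control_relatives()
    save(
        "negative_control_report",
        pd.DataFrame(
            [
                {
                    "prey_id": k,
                    "relative_signal": rs.relative,
                    "n_experiments": rs.n_experiments,
                }
                for k, rs in sorted(nc.items())
            ]
        ),
    )
    fig_path = out / "signal_histograms.png"
    plot_signal_histograms(result, fig_path)
    report.files["signal_histograms"] = fig_path
    logger.info(
        "signals: cut-offs (%.4g, %.4g); %d mutant preys",
        cutoffs.lower,
        cutoffs.upper,
        len(result.mutant_relatives()),
    )

    # --- stage 4: structure mapping ---------------------------------------
    structure = StructureModel.from_pdb(config.structure_pdb)
    per_sub = result.per_substitution
    if per_sub is None or per_sub.empty:
        raise RuntimeError("no single-missense substitutions survived; cannot map")
    pairs = [
        (codon_of_sub[row.substitution], float(row.relative_signal))
        for row in per_sub.itertuples(index=False)
    ]
    attr, unmapped = build_attribute(
        pairs,
        ref,
        name=config.attribute_name,
        reduce=config.residue_reduce,
        structure=structure,
    )
    attr_path = out / f"{config.attribute_name}.txt"
    write_attribute_file(attr, attr_path)
    report.files["attribute"] = attr_path
    if unmapped:
        logger.warning("unmapped residues (absent from structure): %s", unmapped)

    adjacency = residue_adjacency(structure, config.adjacency_cutoff)
    affected_residues = sorted(
        {
            ref.residue_number(codon_of_sub[row.substitution])
            for row in per_sub.itertuples(index=False)
            if row.call != MutantCall.UNCHANGED.value
        }
    )
    patches = detect_patches(affected_residues, adjacency, config.min_patch_size)
    save("patches", patches_to_frame(patches))
    logger.info(
        "mapping: %d affected residues in %d patches (%d isolated)",
        len(affected_residues),
        len(patches),
        sum(p.isolated for p in patches),
    )

    pd.DataFrame(
        [
            {
                "key": "unmapped_residues",
                "value": ";".join(str(r) for r in unmapped),
            },
            {"key": "qc_messages", "value": " | ".join(result.qc_log)},
        ]
    ).to_csv(out / "qc_report.csv", index=False)
    report.files["qc_report"] = out / "qc_report.csv"
    return report


def generate_layout_files(
    dna_plates_csv, out_csv, bait_id: str, experiments: list[str]
) -> pd.DataFrame:
    """Stage command: expand 96-well DNA plate definitions into the 384-well
    layout table for the given experiment labels, applying DNA QC."""
    plates96 = frame_to_dna_plates(pd.read_csv(dna_plates_csv))
    plates384 = []
    for exp in experiments:
        for plate in plates96:
            qc = qc_dna(plate)
            a, b = expand_to_transfection(plate, bait_id, exp, qc_pass=qc)
            plates384.extend([a, b])
    frame = layout_to_frame(plates384)
    frame.to_csv(out_csv, index=False, float_format=FLOAT_FORMAT)
    return frame
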