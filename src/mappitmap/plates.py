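"""96-well DNA plate model and deterministic 384-well transfection layout.

Single-missense clones are consolidated into 96-well DNA plates in which one
full row holds wildtype prey plasmid and one full row a negative-control prey
(12 wells each), leaving up to 72 mutant wells.  Each prey/bait mixture is
transfected into 8 wells of a 384-well plate, 4 of which are stimulated with
cytokine, so one 96-well DNA plate expands into two 384-well plates, each
carrying 6 wildtype mixtures, 6 negative-control mixtures and up to 36 mutant
mixtures.

The physical placement of the 8 wells and of the stimulated half is not
dictated by the assay; this module uses a fixed, auditable geometry: source
well (row r, column c) maps to a 2x4 block of wells (rows 2r..2r+1, columns
4c..4c+3 within its half), with the left 2x2 sub-block stimulated.  The
mapping is invertible, so a layout can be collapsed back to its DNA plate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

ROWS_96 = "ABCDEFGH"
COLS_96 = tuple(range(1, 13))
ROWS_384 = "ABCDEFGHIJKLMNOP"
COLS_384 = tuple(range(1, 25))

OD_RATIO_MIN = 1.8  # OD 260/280 must be strictly above this
WELLS_PER_MIXTURE = 8
STIMULATED_PER_MIXTURE = 4


class LayoutError(ValueError):
    """Malformed plate or layout."""


class WellKind(str, enum.Enum):
    MUTANT = "mutant"
    WILDTYPE = "wildtype"
    NEGATIVE_CONTROL = "negative_control"
    EMPTY = "empty"


@dataclass(frozen=True)
class WellContent:
    kind: WellKind
    clone_id: str | None = None

    @property
    def prey_id(self) -> str | None:
        """Prey identity for a mixture: the clone for mutants, the control
        label otherwise, None for empty wells."""
        if self.kind is WellKind.MUTANT:
            return self.clone_id
        if self.kind is WellKind.EMPTY:
            return None
        return self.kind.value


def well_name(row: str, col: int) -> str:
    return f"{row}{col}"


def parse_well(well: str) -> tuple[str, int]:
    return well[0], int(well[1:])


@dataclass
class DnaPlate96:
    """A consolidated 96-well DNA plate of single-missense prey plasmids.

    One full row is wildtype prey, one full row negative-control prey
    (rows A and H by default), the rest mutant clones or empty.
    """

    plate_id: str
    contents: dict[str, WellContent]
    dna_conc: dict[str, float] = field(default_factory=dict)  # ng/uL
    od_ratio: dict[str, float] = field(default_factory=dict)
    wt_row: str = "A"
    nc_row: str = "H"

    def __post_init__(self) -> None:
        for row in ROWS_96:
            for col in COLS_96:
                self.contents.setdefault(well_name(row, col), WellContent(WellKind.EMPTY))
        self.validate()

    def validate(self) -> None:
        if self.wt_row == self.nc_row:
            raise LayoutError("wildtype and negative-control rows must differ")
        for col in COLS_96:
            if self.contents[well_name(self.wt_row, col)].kind is not WellKind.WILDTYPE:
                raise LayoutError(
                    f"{self.plate_id}: row {self.wt_row} must be all wildtype"
                )
            if self.contents[well_name(self.nc_row, col)].kind is not WellKind.NEGATIVE_CONTROL:
                raise LayoutError(
                    f"{self.plate_id}: row {self.nc_row} must be all negative_control"
                )
        n_wt = sum(1 for c in self.contents.values() if c.kind is WellKind.WILDTYPE)
        n_nc = sum(1 for c in self.contents.values() if c.kind is WellKind.NEGATIVE_CONTROL)
        if n_wt != 12 or n_nc != 12:
            raise LayoutError(
                f"{self.plate_id}: expected exactly 12 wildtype and 12 "
                f"negative-control wells, found {n_wt}/{n_nc}"
            )
        if len(self.mutant_wells()) > 72:
            raise LayoutError(f"{self.plate_id}: more than 72 mutant wells")

    def mutant_wells(self) -> dict[str, str]:
        """Mapping well -> clone_id for all mutant wells (row-major order)."""
        out = {}
        for row in ROWS_96:
            for col in COLS_96:
                w = well_name(row, col)
                if self.contents[w].kind is WellKind.MUTANT:
                    out[w] = self.contents[w].clone_id
        return out

    @classmethod
    def from_clone_ids(
        cls,
        plate_id: str,
        clone_ids: Sequence[str],
        wt_row: str = "A",
        nc_row: str = "H",
        dna_conc: Mapping[str, float] | None = None,
        od_ratio: Mapping[str, float] | None = None,
    ) -> "DnaPlate96":
        """Fill a plate row-major with up to 72 mutant clones plus the two
        control rows."""
        if len(clone_ids) > 72:
            raise LayoutError("at most 72 mutant clones fit on one plate")
        contents: dict[str, WellContent] = {}
        for col in COLS_96:
            contents[well_name(wt_row, col)] = WellContent(WellKind.WILDTYPE)
            contents[well_name(nc_row, col)] = WellContent(WellKind.NEGATIVE_CONTROL)
        it = iter(clone_ids)
        for row in ROWS_96:
            if row in (wt_row, nc_row):
                continue
            for col in COLS_96:
                clone = next(it, None)
                if clone is None:
                    break
                contents[well_name(row, col)] = WellContent(WellKind.MUTANT, clone)
        return cls(
            plate_id=plate_id,
            contents=contents,
            dna_conc=dict(dna_conc or {}),
            od_ratio=dict(od_ratio or {}),
            wt_row=wt_row,
            nc_row=nc_row,
        )


def qc_dna(plate: DnaPlate96, threshold: float = OD_RATIO_MIN, strict: bool = False) -> dict[str, bool]:
    """Per-well DNA purity QC: pass only if OD 260/280 is strictly above the
    threshold (1.8 by default).

    Wells without a recorded OD pass with a warning unless ``strict`` is set,
    in which case a missing measurement is an error.  Failing mutant wells are
    excluded from layout expansion by :func:`expand_to_transfection`.
    """
    result: dict[str, bool] = {}
    for well, content in plate.contents.items():
        if content.kind is WellKind.EMPTY:
            continue
        od = plate.od_ratio.get(well)
        if od is None:
            if strict:
                raise LayoutError(f"{plate.plate_id}:{well} has no OD 260/280 measurement")
            result[well] = True
        else:
            result[well] = od > threshold
    return result


@dataclass(frozen=True)
class Mixture:
    """One unique prey/bait transfection mixture."""

    mixture_id: str
    prey_id: str
    bait_id: str
    kind: WellKind
    source_plate: str
    source_well: str


@dataclass(frozen=True)
class WellAssignment:
    mixture_id: str
    stimulated: bool


@dataclass
class TransfectionPlate384:
    """One 384-well transfection plate: well -> (mixture, stimulated)."""

    plate_id: str
    experiment_id: str
    wells: dict[str, WellAssignment]
    mixtures: dict[str, Mixture]

    def validate(self) -> None:
        per_mix: dict[str, list[WellAssignment]] = {}
        for assignment in self.wells.values():
            if assignment.mixture_id not in self.mixtures:
                raise LayoutError(f"{self.plate_id}: unknown mixture {assignment.mixture_id}")
            per_mix.setdefault(assignment.mixture_id, []).append(assignment)
        if len(per_mix) > 48:
            raise LayoutError(f"{self.plate_id}: more than 48 mixtures")
        for mix_id, assigns in per_mix.items():
            if len(assigns) != WELLS_PER_MIXTURE:
                raise LayoutError(
                    f"{self.plate_id}: mixture {mix_id} occupies {len(assigns)} wells"
                )
            n_stim = sum(a.stimulated for a in assigns)
            if n_stim != STIMULATED_PER_MIXTURE:
                raise LayoutError(
                    f"{self.plate_id}: mixture {mix_id} has {n_stim} stimulated wells"
                )

    def mixtures_of_kind(self, kind: WellKind) -> list[Mixture]:
        return [m for m in self.mixtures.values() if m.kind is kind]

    def wells_of_mixture(self, mixture_id: str) -> dict[str, WellAssignment]:
        return {
            w: a for w, a in self.wells.items() if a.mixture_id == mixture_id
        }


def expand_to_transfection(
    plate: DnaPlate96,
    bait_id: str,
    experiment_id: str,
    qc_pass: Mapping[str, bool] | None = None,
) -> tuple[TransfectionPlate384, TransfectionPlate384]:
    """Expand one 96-well DNA plate into its two 384-well transfection plates.

    Columns 1-6 of the source plate feed the first 384 plate, columns 7-12
    the second; each source well becomes a 2x4 block of 8 wells whose left
    2x2 sub-block is stimulated.  Mutant wells failing DNA QC (``qc_pass``)
    are left out; control wells are always transfected.
    """
    plate.validate()
    halves: list[TransfectionPlate384] = []
    for half in range(2):
        suffix = "A" if half == 0 else "B"
        wells: dict[str, WellAssignment] = {}
        mixtures: dict[str, Mixture] = {}
        for r, row in enumerate(ROWS_96):
            for c_in in range(6):
                col = half * 6 + c_in + 1
                src = well_name(row, col)
                content = plate.contents[src]
                if content.kind is WellKind.EMPTY:
                    continue
                if (
                    content.kind is WellKind.MUTANT
                    and qc_pass is not None
                    and not qc_pass.get(src, True)
                ):
                    continue
                mixture_id = f"{plate.plate_id}:{src}"
                mixtures[mixture_id] = Mixture(
                    mixture_id=mixture_id,
                    prey_id=content.prey_id,
                    bait_id=bait_id,
                    kind=content.kind,
                    source_plate=plate.plate_id,
                    source_well=src,
                )
                for dr in range(2):
                    for dc in range(4):
                        w384 = well_name(ROWS_384[2 * r + dr], 4 * c_in + dc + 1)
                        wells[w384] = WellAssignment(
                            mixture_id=mixture_id, stimulated=dc < 2
                        )
        p384 = TransfectionPlate384(
            plate_id=f"{experiment_id}:{plate.plate_id}:{suffix}",
            experiment_id=experiment_id,
            wells=wells,
            mixtures=mixtures,
        )
        p384.validate()
        halves.append(p384)
    return halves[0], halves[1]


def collapse_transfection(
    plate_a: TransfectionPlate384, plate_b: TransfectionPlate384
) -> dict[str, WellContent]:
    """Invert :func:`expand_to_transfection`: recover the source 96-well
    contents (QC-excluded and empty wells come back as empty)."""
    contents: dict[str, WellContent] = {
        well_name(r, c): WellContent(WellKind.EMPTY) for r in ROWS_96 for c in COLS_96
    }
    for p384 in (plate_a, plate_b):
        for mixture in p384.mixtures.values():
            clone = mixture.prey_id if mixture.kind is WellKind.MUTANT else None
            contents[mixture.source_well] = WellContent(mixture.kind, clone)
    return contents


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def layout_to_frame(plates: Iterable[TransfectionPlate384]) -> pd.DataFrame:
    """Flat layout table: one row per non-empty 384 well."""
    rows = []
    for p in plates:
        for well in sorted(p.wells, key=parse_well):
            a = p.wells[well]
            m = p.mixtures[a.mixture_id]
            rows.append(
                {
                    "experiment_id": p.experiment_id,
                    "plate_id": p.plate_id,
                    "well": well,
                    "mixture_id": a.mixture_id,
                    "stimulated": int(a.stimulated),
                    "prey_kind": m.kind.value,
                    "prey_id": m.prey_id,
                    "bait_id": m.bait_id,
                    "source_plate": m.source_plate,
                    "source_well": m.source_well,
                }
            )
    return pd.DataFrame(rows)


def frame_to_layout(frame: pd.DataFrame) -> list[TransfectionPlate384]:
    """Rebuild TransfectionPlate384 objects from a flat layout table."""
    plates = []
    for plate_id, sub in frame.groupby("plate_id", sort=True):
        wells: dict[str, WellAssignment] = {}
        mixtures: dict[str, Mixture] = {}
        experiment_id = str(sub["experiment_id"].iloc[0])
        for row in sub.itertuples(index=False):
            wells[row.well] = WellAssignment(
                mixture_id=row.mixture_id, stimulated=bool(row.stimulated)
            )
            if row.mixture_id not in mixtures:
                mixtures[row.mixture_id] = Mixture(
                    mixture_id=row.mixture_id,
                    prey_id=str(row.prey_id),
                    bait_id=str(row.bait_id),
                    kind=WellKind(row.prey_kind),
                    source_plate=str(row.source_plate),
                    source_well=str(row.source_well),
                )
        plate = TransfectionPlate384(
            plate_id=str(plate_id),
            experiment_id=experiment_id,
            wells=wells,
            mixtures=mixtures,
        )
        plate.validate()
        plates.append(plate)
    return plates


def dna_plate_to_frame(plate: DnaPlate96) -> pd.DataFrame:
    rows = []
    for row in ROWS_96:
        for col in COLS_96:
            w = well_name(row, col)
            content = plate.contents[w]
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": w,
                    "kind": content.kind.value,
                    "clone_id": content.clone_id or "",
                    "dna_conc": plate.dna_conc.get(w, float("nan")),
                    "od_ratio": plate.od_ratio.get(w, float("nan")),
                }
            )
    return pd.DataFrame(rows)


def frame_to_dna_plates(frame: pd.DataFrame) -> list[DnaPlate96]:
    plates = []
    for plate_id, sub in frame.groupby("plate_id", sort=True):
        contents: dict[str, WellContent] = {}
        dna_conc: dict[str, float] = {}
        od_ratio: dict[str, float] = {}
        for row in sub.itertuples(index=False):
            kind = WellKind(row.kind)
            clone = str(row.clone_id) if kind is WellKind.MUTANT else None
            contents[row.well] = WellContent(kind, clone)
            if pd.notna(row.dna_conc):
                dna_conc[row.well] = float(row.dna_conc)
            if pd.notna(row.od_ratio):
                od_ratio[row.well] = float(row.od_ratio)
        wt_row = next(
            r for r in ROWS_96
            if all(contents[well_name(r, c)].kind is WellKind.WILDTYPE for c in COLS_96)
        )
        nc_row = next(
            r for r in ROWS_96
            if all(contents[well_name(r, c)].kind is WellKind.NEGATIVE_CONTROL for c in COLS_96)
        )
        plates.append(
            DnaPlate96(
                plate_id=str(plate_id),
                contents=contents,
                dna_conc=dna_conc,
                od_ratio=od_ratio,
                wt_row=wt_row,
                nc_row=nc_row,
            )
        )
    return plates
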