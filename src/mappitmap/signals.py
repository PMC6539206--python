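"""The three-stage MAPPIT statistic, wildtype cut-offs and mutant calls.

For each prey/bait mixture the *MAPPIT signal* is the ratio of the mean
luciferase counts of its 4 stimulated wells to the mean of its 4 unstimulated
wells.  The *normalized MAPPIT signal* divides that ratio by the median MAPPIT
signal of the 6 wildtype mixtures on the same 384-well plate, cancelling
plate-wide multiplicative effects.  The *relative MAPPIT signal* of a prey is
the mean of its normalized signals across the (target three) replicate
transfection experiments.

Wildtype preys are themselves normalized leave-one-out — each against the
median of the 5 other wildtypes on its plate — and the minimum and maximum
wildtype relative signal across the screen become the lower and upper cut-off.
A mutant strictly below the lower cut-off is called ``decreased``, strictly
above the upper cut-off ``increased``, otherwise ``unchanged``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plates import TransfectionPlate384, WellKind

FOLD_INDUCTION_MIN = 10.0  # assay QC: wildtype induction must be >= 10-fold
MIN_WELLS_PER_ARM = 3      # tolerate one missing well per arm
MIN_WILDTYPES_PER_PLATE = 4
TARGET_EXPERIMENTS = 3


class SignalError(ValueError):
    """Base class for signal-pipeline errors."""


class UndefinedSignalError(SignalError):
    """Unstimulated mean is zero: the ratio is undefined."""


class PlateQCError(SignalError):
    """A 384 plate fails wildtype-based QC and cannot be normalized."""


@dataclass(frozen=True)
class MixtureSignal:
    """MAPPIT signal of one mixture on one plate: mean(stim)/mean(unstim)."""

    mixture_id: str
    plate_id: str
    mappit_signal: float
    mean_stim: float
    mean_unstim: float
    n_stim: int
    n_unstim: int


@dataclass(frozen=True)
class CutoffPair:
    """Screen-wide decision thresholds from the wildtype relative signals."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise SignalError(f"invalid cut-offs ({self.lower}, {self.upper})")


class MutantCall(str, enum.Enum):
    DECREASED = "decreased"
    UNCHANGED = "unchanged"
    INCREASED = "increased"


@dataclass(frozen=True)
class RelativeSignal:
    """Replicate-averaged normalized signal for one prey."""

    prey_id: str
    per_experiment: tuple[float, ...]
    relative: float
    n_experiments: int

    @property
    def incomplete(self) -> bool:
        return self.n_experiments < TARGET_EXPERIMENTS


def compute_mappit_signal(
    stim_counts: Sequence[float],
    unstim_counts: Sequence[float],
    mixture_id: str = "",
    plate_id: str = "",
    min_wells_per_arm: int = MIN_WELLS_PER_ARM,
) -> MixtureSignal:
    """Ratio of arithmetic means, stimulated over unstimulated wells.

    Raises
    ------
    SignalError
        If either arm has fewer than ``min_wells_per_arm`` readings.
    UndefinedSignalError
        If the unstimulated mean is zero.
    """
    stim = np.asarray(stim_counts, dtype=float)
    unstim = np.asarray(unstim_counts, dtype=float)
    if stim.size < min_wells_per_arm or unstim.size < min_wells_per_arm:
        raise SignalError(
            f"mixture {mixture_id}: only {stim.size} stimulated / "
            f"{unstim.size} unstimulated wells (minimum {min_wells_per_arm})"
        )
    mean_stim = float(stim.mean())
    mean_unstim = float(unstim.mean())
    if mean_unstim == 0:
        raise UndefinedSignalError(
            f"mixture {mixture_id}: unstimulated mean is zero"
        )
    return MixtureSignal(
        mixture_id=mixture_id,
        plate_id=plate_id,
        mappit_signal=mean_stim / mean_unstim,
        mean_stim=mean_stim,
        mean_unstim=mean_unstim,
        n_stim=int(stim.size),
        n_unstim=int(unstim.size),
    )


def compute_plate_signals(
    plate: TransfectionPlate384,
    counts: Mapping[str, float],
    min_wells_per_arm: int = MIN_WELLS_PER_ARM,
) -> tuple[dict[str, MixtureSignal], list[str]]:
    """MAPPIT signal for every mixture of one plate.

    ``counts`` maps well name -> luminescence counts per second; wells absent
    from the mapping are treated as missing.  Returns the per-mixture signals
    and a log of excluded mixtures (too many missing wells, or an undefined
    ratio).
    """
    per_mixture: dict[str, tuple[list[float], list[float]]] = {
        m: ([], []) for m in plate.mixtures
    }
    for well, assignment in plate.wells.items():
        if well not in counts:
            continue
        value = float(counts[well])
        if value < 0:
            raise SignalError(f"{plate.plate_id}:{well}: negative counts")
        arm = 0 if assignment.stimulated else 1
        per_mixture[assignment.mixture_id][arm].append(value)
    signals: dict[str, MixtureSignal] = {}
    log: list[str] = []
    for mixture_id in sorted(per_mixture):
        stim, unstim = per_mixture[mixture_id]
        try:
            signals[mixture_id] = compute_mappit_signal(
                stim, unstim, mixture_id, plate.plate_id, min_wells_per_arm
            )
        except SignalError as exc:
            log.append(f"excluded: {exc}")
    return signals, log


def qc_fold_induction(
    wildtype_signal: float, minimum: float = FOLD_INDUCTION_MIN
) -> bool:
    """Assay QC gate: wildtype induction must be at least ``minimum``-fold
    (inclusive)."""
    return wildtype_signal >= minimum


def _median(values: Sequence[float]) -> float:
    # numpy convention: even n -> mean of the two central order statistics
    return float(np.median(np.asarray(values, dtype=float)))


def normalize_on_plate(
    signals: Mapping[str, MixtureSignal],
    wildtype_ids: Iterable[str],
    min_wildtypes: int = MIN_WILDTYPES_PER_PLATE,
) -> dict[str, float]:
    """Divide every non-wildtype signal by the plate's wildtype median.

    Raises :class:`PlateQCError` if fewer than ``min_wildtypes`` wildtype
    signals are present or their median is zero.
    """
    wt_ids = [w for w in wildtype_ids if w in signals]
    if len(wt_ids) < min_wildtypes:
        raise PlateQCError(
            f"only {len(wt_ids)} wildtype signals on plate (minimum {min_wildtypes})"
        )
    wt_median = _median([signals[w].mappit_signal for w in wt_ids])
    if wt_median == 0:
        raise PlateQCError("wildtype median MAPPIT signal is zero")
    return {
        mix_id: sig.mappit_signal / wt_median
        for mix_id, sig in signals.items()
        if mix_id not in set(wt_ids)
    }


def wt_loo_normalize(
    wildtype_signals: Mapping[str, float]
) -> dict[str, float]:
    """Leave-one-out normalization of the wildtype signals of one plate:
    each wildtype is divided by the median of the other wildtypes."""
    ids = sorted(wildtype_signals)
    if len(ids) < 2:
        raise PlateQCError("leave-one-out normalization needs >= 2 wildtypes")
    out: dict[str, float] = {}
    for wt in ids:
        others = [wildtype_signals[w] for w in ids if w != wt]
        med = _median(others)
        if med == 0:
            raise PlateQCError("leave-one-out wildtype median is zero")
        out[wt] = wildtype_signals[wt] / med
    return out


def aggregate_replicates(
    prey_id: str, per_experiment: Sequence[float]
) -> RelativeSignal:
    """Average the normalized signals of one prey across experiments."""
    if len(per_experiment) == 0:
        raise SignalError(f"prey {prey_id}: no experiments to aggregate")
    values = tuple(float(v) for v in per_experiment)
    return RelativeSignal(
        prey_id=prey_id,
        per_experiment=values,
        relative=float(np.mean(values)),
        n_experiments=len(values),
    )


def derive_cutoffs(wildtype_relatives: Sequence[float]) -> CutoffPair:
    """Lower/upper cut-off = min/max wildtype relative signal of the screen."""
    if len(wildtype_relatives) < 2:
        raise SignalError("cut-offs need >= 2 wildtype relative signals")
    return CutoffPair(
        lower=float(min(wildtype_relatives)), upper=float(max(wildtype_relatives))
    )


def classify_relative(relative: float, cutoffs: CutoffPair) -> MutantCall:
    """Strictly below the lower cut-off -> decreased; strictly above the
    upper -> increased; boundary values are unchanged."""
    if relative < cutoffs.lower:
        return MutantCall.DECREASED
    if relative > cutoffs.upper:
        return MutantCall.INCREASED
    return MutantCall.UNCHANGED


def classify_mutants(
    relatives: Mapping[str, RelativeSignal], cutoffs: CutoffPair
) -> dict[str, MutantCall]:
    return {
        prey: classify_relative(rs.relative, cutoffs)
        for prey, rs in relatives.items()
    }


# ---------------------------------------------------------------------------
# Screen-level orchestration
# ---------------------------------------------------------------------------

def _prey_key(mixture) -> str:
    """Replicate-tracking identity of a prey.

    Mutant mixtures aggregate by clone; each wildtype / negative-control
    source well is its own track (the same source well recurs across
    experiments), so wildtype relative signals stay per-wildtype-prey.
    """
    if mixture.kind is WellKind.MUTANT:
        return mixture.prey_id
    return f"{mixture.kind.value}@{mixture.source_plate}:{mixture.source_well}"


@dataclass
class ScreenResult:
    """All tables of a screen analysis.

    ``relatives``/``calls`` are per prey track (clone, or control well);
    ``per_substitution`` averages clone-level relative signals of clones that
    carry the same amino-acid substitution.
    """

    mixture_signals: pd.DataFrame
    relatives: dict[str, RelativeSignal]
    kinds: dict[str, WellKind]
    cutoffs: CutoffPair
    calls: dict[str, MutantCall]
    per_substitution: pd.DataFrame | None
    qc_log: list[str] = field(default_factory=list)

    def wildtype_relatives(self) -> dict[str, RelativeSignal]:
        return {
            k: v for k, v in self.relatives.items()
            if self.kinds[k] is WellKind.WILDTYPE
        }

    def mutant_relatives(self) -> dict[str, RelativeSignal]:
        return {
            k: v for k, v in self.relatives.items()
            if self.kinds[k] is WellKind.MUTANT
        }

    def negative_control_relatives(self) -> dict[str, RelativeSignal]:
        return {
            k: v for k, v in self.relatives.items()
            if self.kinds[k] is WellKind.NEGATIVE_CONTROL
        }

    def relatives_frame(self) -> pd.DataFrame:
        rows = []
        for prey in sorted(self.relatives):
            rs = self.relatives[prey]
            rows.append(
                {
                    "prey_id": prey,
                    "kind": self.kinds[prey].value,
                    "relative_signal": rs.relative,
                    "n_experiments": rs.n_experiments,
                    "incomplete": int(rs.incomplete),
                    "call": self.calls[prey].value,
                    "per_experiment": ";".join(f"{v:.6g}" for v in rs.per_experiment),
                }
            )
        return pd.DataFrame(rows)


def analyze_screen(
    plates: Sequence[TransfectionPlate384],
    readings: pd.DataFrame,
    substitution_map: Mapping[str, str] | None = None,
    min_wells_per_arm: int = MIN_WELLS_PER_ARM,
    min_wildtypes: int = MIN_WILDTYPES_PER_PLATE,
    fold_induction_min: float = FOLD_INDUCTION_MIN,
) -> ScreenResult:
    """Run the full statistic over a multi-plate, multi-experiment screen.

    Parameters
    ----------
    plates
        All 384-well layouts of the screen; plate IDs must be unique and each
        plate carries its experiment label.
    readings
        Long table with columns ``plate_id, well, counts``.
    substitution_map
        Optional clone_id -> amino-acid substitution label (e.g. ``"P163L"``);
        when given, clone-level relative signals are additionally averaged per
        substitution and re-classified at that level.
    """
    qc_log: list[str] = []
    counts_by_plate = {
        str(pid): dict(zip(sub["well"], sub["counts"]))
        for pid, sub in readings.groupby("plate_id")
    }

    signal_rows = []
    # prey_key -> experiment -> list of normalized values (several plates of
    # one experiment may carry the same clone; averaged within experiment)
    normalized: dict[str, dict[str, list[float]]] = {}
    kinds: dict[str, WellKind] = {}

    for plate in sorted(plates, key=lambda p: p.plate_id):
        counts = counts_by_plate.get(plate.plate_id)
        if counts is None:
            qc_log.append(f"plate {plate.plate_id}: no readings, skipped")
            continue
        signals, excl = compute_plate_signals(counts=counts, plate=plate, min_wells_per_arm=min_wells_per_arm)
        qc_log.extend(f"plate {plate.plate_id}: {msg}" for msg in excl)

        wt_ids = sorted(
            m.mixture_id for m in plate.mixtures_of_kind(WellKind.WILDTYPE)
        )
        wt_signals = {
            w: signals[w].mappit_signal for w in wt_ids if w in signals
        }
        if wt_signals:
            wt_med = _median(list(wt_signals.values()))
            if not qc_fold_induction(wt_med, fold_induction_min):
                qc_log.append(
                    f"plate {plate.plate_id}: wildtype fold induction "
                    f"{wt_med:.2f} below the {fold_induction_min:g}-fold gate"
                )
        try:
            norm = normalize_on_plate(signals, wt_ids, min_wildtypes)
            loo = wt_loo_normalize(wt_signals)
        except PlateQCError as exc:
            qc_log.append(f"plate {plate.plate_id}: QC failure, dropped ({exc})")
            continue

        for mix_id, sig in signals.items():
            mixture = plate.mixtures[mix_id]
            value = loo.get(mix_id) if mix_id in loo else norm.get(mix_id)
            signal_rows.append(
                {
                    "experiment_id": plate.experiment_id,
                    "plate_id": plate.plate_id,
                    "mixture_id": mix_id,
                    "prey_id": mixture.prey_id,
                    "kind": mixture.kind.value,
                    "mean_stim": sig.mean_stim,
                    "mean_unstim": sig.mean_unstim,
                    "n_stim": sig.n_stim,
                    "n_unstim": sig.n_unstim,
                    "mappit_signal": sig.mappit_signal,
                    "normalized_signal": value,
                }
            )
            key = _prey_key(mixture)
            kinds[key] = mixture.kind
            normalized.setdefault(key, {}).setdefault(
                plate.experiment_id, []
            ).append(float(value))

    if not normalized:
        raise SignalError("no mixture survived plate QC; nothing to analyze")

    relatives: dict[str, RelativeSignal] = {}
    for key in sorted(normalized):
        per_exp = [
            float(np.mean(vals)) for _exp, vals in sorted(normalized[key].items())
        ]
        rs = aggregate_replicates(key, per_exp)
        relatives[key] = rs
        if rs.incomplete:
            qc_log.append(
                f"prey {key}: only {rs.n_experiments} of "
                f"{TARGET_EXPERIMENTS} experiments"
            )

    wt_rel = [
        rs.relative for k, rs in relatives.items()
        if kinds[k] is WellKind.WILDTYPE
    ]
    cutoffs = derive_cutoffs(wt_rel)
    calls = classify_mutants(relatives, cutoffs)

    per_sub = None
    if substitution_map is not None:
        sub_values: dict[str, list[float]] = {}
        for key, rs in relatives.items():
            if kinds[key] is not WellKind.MUTANT:
                continue
            label = substitution_map.get(key)
            if label is None:
                qc_log.append(f"clone {key}: no substitution label, left out of per-substitution table")
                continue
            sub_values.setdefault(label, []).append(rs.relative)
        rows = []
        for label in sorted(sub_values):
            mean_rel = float(np.mean(sub_values[label]))
            rows.append(
                {
                    "substitution": label,
                    "relative_signal": mean_rel,
                    "n_clones": len(sub_values[label]),
                    "call": classify_relative(mean_rel, cutoffs).value,
                }
            )
        per_sub = pd.DataFrame(rows)

    return ScreenResult(
        mixture_signals=pd.DataFrame(signal_rows),
        relatives=relatives,
        kinds=kinds,
        cutoffs=cutoffs,
        calls=calls,
        per_substitution=per_sub,
        qc_log=qc_log,
    )


def plot_signal_histograms(result: ScreenResult, path) -> None:
    """Histograms of wildtype and mutant relative signals with the cut-offs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wt = [rs.relative for rs in result.wildtype_relatives().values()]
    mut = [rs.relative for rs in result.mutant_relatives().values()]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, values, title in (
        (axes[0], wt, "wildtype preys"),
        (axes[1], mut, "mutant preys"),
    ):
        if values:
            ax.hist(values, bins=30, color="#4878a8", edgecolor="black")
        ax.axvline(result.cutoffs.lower, color="red", ls="--", lw=1)
        ax.axvline(result.cutoffs.upper, color="red", ls="--", lw=1)
        ax.set_title(title)
        ax.set_xlabel("relative MAPPIT signal")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
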