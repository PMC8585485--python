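"""Stage-level time-bins for the Early Permian - Middle Triassic interval.

The default scheme covers the Asselian through the Ladinian (298-237 Ma)
in 12 bins.  The Induan and Olenekian are short stages and are merged
into a single Early Triassic bin, so the 13 ICS stages map onto 12 bins.
Bins are grouped into five epochs: Early/Middle/Late Permian (P1, P2,
P3), Early Triassic (T1) and Middle Triassic (T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TimeBin:
    """One stage-level bin. ``index`` 0 is the oldest; ages in Ma."""

    name: str
    index: int
    age_max: float  # older bound
    age_min: float  # younger bound

    def __post_init__(self) -> None:
        if not self.age_max > self.age_min:
            raise ValueError(
                f"bin {self.name!r}: age_max ({self.age_max}) must exceed "
                f"age_min ({self.age_min})"
            )


# (bin name, older bound Ma, younger bound Ma, epoch code)
# Internal boundaries follow the ICS chart; the outer bounds are pinned
# to the 298-237 Ma span of the study interval.
_DEFAULT_BINS = [
    ("Asselian", 298.0, 293.52, "P1"),
    ("Sakmarian", 293.52, 290.1, "P1"),
    ("Artinskian", 290.1, 283.5, "P1"),
    ("Kungurian", 283.5, 273.01, "P1"),
    ("Roadian", 273.01, 266.9, "P2"),
    ("Wordian", 266.9, 264.28, "P2"),
    ("Capitanian", 264.28, 259.51, "P2"),
    ("Wuchiapingian", 259.51, 254.14, "P3"),
    ("Changhsingian", 254.14, 251.9, "P3"),
    ("Induan+Olenekian", 251.9, 247.2, "T1"),
    ("Anisian", 247.2, 242.0, "T2"),
    ("Ladinian", 242.0, 237.0, "T2"),
]

# Stage name -> bin name.  The two Early Triassic stages share a bin.
_STAGE_TO_BIN = {name: name for name, *_ in _DEFAULT_BINS if "+" not in name}
_STAGE_TO_BIN["Induan"] = "Induan+Olenekian"
_STAGE_TO_BIN["Olenekian"] = "Induan+Olenekian"
_STAGE_TO_BIN["Induan+Olenekian"] = "Induan+Olenekian"

EPOCH_CODES = ("P1", "P2", "P3", "T1", "T2")


class UnknownStageError(KeyError):
    """A stage name that does not resolve to any bin of the scheme."""


@dataclass(frozen=True)
class TimeBinScheme:
    """An ordered, contiguous sequence of time-bins plus epoch labels.

    ``epoch_labels`` maps bin name to one of the epoch codes P1, P2, P3,
    T1, T2; ``stage_map`` maps resolvable stage names to bin names.
    """

    bins: tuple[TimeBin, ...]
    epoch_labels: dict[str, str] = field(default_factory=dict)
    stage_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for older, younger in zip(self.bins, self.bins[1:]):
            if younger.index != older.index + 1:
                raise ValueError("bin indices must increase by 1 with decreasing age")
            if abs(older.age_min - younger.age_max) > 1e-9:
                raise ValueError(
                    f"bins {older.name!r} and {younger.name!r} are not contiguous"
                )

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    def bin_by_name(self, name: str) -> TimeBin:
        for b in self.bins:
            if b.name == name:
                return b
        raise UnknownStageError(name)

    def resolve_stage(self, stage: str) -> TimeBin:
        """Map a (global chronostratigraphic) stage name to its bin.

        Local stratigraphic names are deliberately not converted; input
        databases must already use global stage names.
        """
        key = stage.strip()
        if key not in self.stage_map:
            raise UnknownStageError(stage)
        return self.bin_by_name(self.stage_map[key])

    def epoch_of(self, bin_index: int) -> str:
        return self.epoch_labels[self.bins[bin_index].name]

    def bins_of_epoch(self, epoch: str) -> list[TimeBin]:
        return [b for b in self.bins if self.epoch_labels[b.name] == epoch]


def build_default_bins() -> TimeBinScheme:
    """The 12-bin Asselian-Ladinian scheme with merged Induan+Olenekian."""
    bins = tuple(
        TimeBin(name=name, index=i, age_max=amax, age_min=amin)
        for i, (name, amax, amin, _) in enumerate(_DEFAULT_BINS)
    )
    epochs = {name: epoch for name, _, _, epoch in _DEFAULT_BINS}
    return TimeBinScheme(bins=bins, epoch_labels=epochs, stage_map=dict(_STAGE_TO_BIN))
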