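"""Stimulus catalogs for voice-localizer style experiments.

The experimental design crossed two main sound categories (human vocal
vs. non-vocal) each split into two subcategories — speech and non-speech
vocal sounds on the vocal side, natural and artificial sounds on the
non-vocal side — with the same number of stimuli per subcategory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

MAIN_CATEGORIES = ("vocal", "nonvocal")
SUBCATEGORIES = ("speech", "nonspeech_vocal", "natural", "artificial")

#: Which main category each subcategory belongs to.
SUBCATEGORY_PARENT = {
    "speech": "vocal",
    "nonspeech_vocal": "vocal",
    "natural": "nonvocal",
    "artificial": "nonvocal",
}


@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    main_category: str
    subcategory: str
    waveform_ref: Optional[str] = None

    def __post_init__(self):
        if self.subcategory not in SUBCATEGORY_PARENT:
            raise InvalidArgumentError(f"unknown subcategory {self.subcategory!r}")
        if self.main_category != SUBCATEGORY_PARENT[self.subcategory]:
            raise InvalidArgumentError(
                f"subcategory {self.subcategory!r} implies main category "
                f"{SUBCATEGORY_PARENT[self.subcategory]!r}, got {self.main_category!r}"
            )


@dataclass(frozen=True)
class StimulusSet:
    """An ordered, immutable catalog of sound stimuli."""

    stimuli: tuple[Stimulus, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("stimulus_id values must be unique")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    def subset(self, subcategory: str) -> list[Stimulus]:
        return [s for s in self.stimuli if s.subcategory == subcategory]

    def by_main_category(self, main_category: str) -> list[Stimulus]:
        return [s for s in self.stimuli if s.main_category == main_category]

    def is_vocal(self) -> np.ndarray:
        """Boolean mask over stimuli, True for vocal sounds."""
        return np.array([s.main_category == "vocal" for s in self.stimuli])

    def with_waveforms(self, refs: dict[str, str]) -> "StimulusSet":
        """Return a copy with waveform paths attached by stimulus id."""
        new = tuple(
            replace(s, waveform_ref=refs.get(s.stimulus_id, s.waveform_ref))
            for s in self.stimuli
        )
        return StimulusSet(new)

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": [s.stimulus_id for s in self.stimuli],
                "main_category": [s.main_category for s in self.stimuli],
                "subcategory": [s.subcategory for s in self.stimuli],
                "waveform_ref": [s.waveform_ref or "" for s in self.stimuli],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StimulusSet":
        stimuli = tuple(
            Stimulus(
                stimulus_id=str(row.stimulus_id),
                main_category=str(row.main_category),
                subcategory=str(row.subcategory),
                waveform_ref=(str(row.waveform_ref) or None)
                if "waveform_ref" in df.columns and not pd.isna(row.waveform_ref)
                else None,
            )
            for row in df.itertuples()
        )
        return cls(stimuli)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StimulusSet":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df["waveform_ref"] = df.get("waveform_ref", pd.Series(dtype=str)).replace("", None)
        return cls.from_dataframe(df)


def generate_stimulus_set(n_per_subcategory: int, seed: int = 0) -> StimulusSet:
    """Build a balanced stimulus catalog with ``n_per_subcategory`` sounds
    in each of the four subcategories.

    Ids are deterministic (``speech_00`` ...). ``seed`` fixes the catalog
    order, which is shuffled so that category structure is not confounded
    with presentation order.
    """
    if n_per_subcategory < 1:
        raise InvalidArgumentError("n_per_subcategory must be >= 1")
    stimuli = [
        Stimulus(
            stimulus_id=f"{sub}_{i:02d}",
            main_category=SUBCATEGORY_PARENT[sub],
            subcategory=sub,
        )
        for sub in SUBCATEGORIES
        for i in range(n_per_subcategory)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stimuli))
    return StimulusSet(tuple(stimuli[i] for i in order))
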