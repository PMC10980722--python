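"""Task structure shared by the simulator and the first-level models.

The paradigm is an implicit emotional-face task with five expression
conditions presented in an event-related design over two runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the five expression conditions, fixed order used everywhere
CONDITIONS: tuple[str, ...] = ("angry", "fear", "happy", "neutral", "sad")

EVENT_COLUMNS = ["onset", "duration", "trial_type", "stimulus_id"]


@dataclass
class EventSchedule:
    """Per-run event tables (onset_s, duration_s, condition, stimulus_id).

    Each run is a DataFrame with columns ``onset``, ``duration``,
    ``trial_type`` and ``stimulus_id``; onsets are strictly increasing
    within a run.
    """

    runs: list[pd.DataFrame] = field(repr=False)

    def __post_init__(self) -> None:
        for r, df in enumerate(self.runs):
            missing = [c for c in EVENT_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"run {r}: missing event columns {missing}")
            onsets = df["onset"].to_numpy(dtype=float)
            if onsets.size and not (np.diff(onsets) > 0).all():
                raise ValueError(f"run {r}: onsets must be strictly increasing")
            bad = set(df["trial_type"]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"run {r}: unknown conditions {sorted(bad)}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_events(self) -> int:
        return sum(len(df) for df in self.runs)

    def conditions_present(self, run: int) -> list[str]:
        """Conditions with at least one event in ``run``, canonical order."""
        present = set(self.runs[run]["trial_type"])
        return [c for c in CONDITIONS if c in present]

    # -- I/O (BIDS-like events.tsv) -------------------------------------

    def to_tsv(self, directory: str | Path, prefix: str = "task") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for r, df in enumerate(self.runs, start=1):
            path = directory / f"{prefix}_run-{r:02d}_events.tsv"
            df.to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths

    @classmethod
    def from_tsv(cls, paths: list[str | Path]) -> "EventSchedule":
        return cls(runs=[pd.read_csv(p, sep="\t") for p in paths])
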