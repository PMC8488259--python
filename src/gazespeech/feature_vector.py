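"""Named, group-tagged feature vectors shared by the eye and language extractors."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractViolationError


@dataclass
class FeatureVector:
    """Ordered map of feature name -> value for one (participant, task, modality).

    Missing features are explicitly NaN, never silently zero: the schema
    always lists every feature name, so absence of information is
    distinguishable from a measured zero.
    """

    task: str
    modality: str  # "eye" | "language"
    participant_id: str | None = None
    values: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def add(self, group: str, name: str, value: float) -> None:
        if name in self.values:
            raise ContractViolationError(f"duplicate feature name: {name!r}")
        self.values[name] = float(value)
        self.groups[name] = group

    def update(self, other: "FeatureVector") -> "FeatureVector":
        for name, value in other.values.items():
            self.add(other.groups[name], name, value)
        return self

    def group_sizes(self) -> dict:
        sizes: dict = {}
        for g in self.groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)
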