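"""The clinical-pathology endpoint panel.

The default panel is the 38-measurement rat panel used throughout the
package: 21 clinical-chemistry and 17 hematology endpoints, five of which
(Neu, Eos, Bas, Mono, Lym) form the white-blood-cell differential whose
percentages must plausibly sum to ~100%. The panel's order is fixed — it
defines the indexing of every profile vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Iterable

import pandas as pd

CATEGORIES = ("clinical_chemistry", "hematology")

#: canonical WBC differential codes
WBC_CODES = ("Neu", "Eos", "Bas", "Mono", "Lym")


@dataclass(frozen=True)
class Endpoint:
    code: str
    name: str
    category: str
    units: str
    wbc_component: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown endpoint category {self.category!r}")


@dataclass(frozen=True)
class EndpointPanel:
    """An ordered catalogue of endpoints; order defines vector indexing."""

    endpoints: tuple[Endpoint, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        codes = [e.code for e in self.endpoints]
        if len(set(codes)) != len(codes):
            raise ValueError("endpoint codes must be unique")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(codes)})

    def __len__(self) -> int:
        return len(self.endpoints)

    def __iter__(self):
        return iter(self.endpoints)

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.endpoints]

    def index(self, code: str) -> int:
        return self._index[code]

    @property
    def wbc_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.endpoints) if e.wbc_component]

    @property
    def wbc_codes(self) -> list[str]:
        return [e.code for e in self.endpoints if e.wbc_component]

    def subset(self, codes: Iterable[str]) -> "EndpointPanel":
        keep = set(codes)
        return EndpointPanel(tuple(e for e in self.endpoints if e.code in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [e.code for e in self.endpoints],
                "name": [e.name for e in self.endpoints],
                "category": [e.category for e in self.endpoints],
                "units": [e.units for e in self.endpoints],
                "wbc_component": [int(e.wbc_component) for e in self.endpoints],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EndpointPanel":
        eps = tuple(
            Endpoint(
                code=str(r.code),
                name=str(r.name),
                category=str(r.category),
                units=str(r.units),
                wbc_component=bool(int(r.wbc_component)),
            )
            for r in df.itertuples(index=False)
        )
        return cls(eps)

    @classmethod
    def from_csv(cls, path) -> "EndpointPanel":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def default_panel() -> EndpointPanel:
    """The packaged 38-endpoint rat clinical-pathology panel."""
    with _ilres.files("toxgan.resources").joinpath("endpoints.csv").open() as fh:
        panel = EndpointPanel.from_csv(fh)
    assert len(panel) == 38
    return panel
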