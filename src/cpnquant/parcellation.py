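"""Cortical area vocabulary, region grouping, and interhemispheric homotopy.

A :class:`Parcellation` names the cortical areas a charting experiment can
attribute label to, assigns each a region class (prefrontal, premotor,
frontal opercular, parietal, cingulate, F1, or other), and defines the
homotopy relation between hemispheres.  Homotopy is the identity on area
names: area X of one hemisphere is homotopic to area X of the other.

Injection sites are sometimes charted at a finer grain than the labeling
(e.g. an injection confined to the rostral subfield of area 46d, recorded
as ``"46d (r)"``, while labeled neurons are attributed to ``"46d"`` as a
whole).  Such subfield units carry a ``parent`` pointing at their area-level
unit; :meth:`Parcellation.homotopy_target` maps any unit to the area-level
name used when counting homotopic neurons in the opposite hemisphere.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "REGIONS",
    "CorticalArea",
    "Parcellation",
    "UnknownAreaError",
    "default_parcellation",
]

#: Closed set of region classes.  F1 (primary motor cortex) is deliberately
#: its own class: quantitative comparisons of "frontal motor" areas exclude it.
REGIONS = frozenset(
    {
        "prefrontal",
        "premotor",
        "frontal_opercular",
        "parietal",
        "cingulate",
        "F1",
        "other",
    }
)


class UnknownAreaError(KeyError):
    """Raised when an area label does not resolve against a parcellation."""

    def __init__(self, name: str, candidates: Iterable[str]):
        self.name = name
        self.suggestions = difflib.get_close_matches(name, list(candidates), n=3, cutoff=0.0)
        msg = f"unknown cortical area {name!r}"
        if self.suggestions:
            msg += f"; closest known labels: {', '.join(self.suggestions)}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class CorticalArea:
    """One named cortical area (or injection subfield) with its region class."""

    name: str
    region: str
    parent: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("area name must be non-empty")
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {sorted(REGIONS)}")


@dataclass
class Parcellation:
    """Ordered collection of :class:`CorticalArea` with unique names."""

    areas: list[CorticalArea] = field(default_factory=list)
    version: str = ""

    def __post_init__(self) -> None:
        self._by_name: dict[str, CorticalArea] = {}
        for area in self.areas:
            if area.name in self._by_name:
                raise ValueError(f"duplicate area name {area.name!r}")
            self._by_name[area.name] = area
        for area in self.areas:
            if area.parent is not None and area.parent not in self._by_name:
                raise ValueError(
                    f"area {area.name!r} names unknown parent {area.parent!r}"
                )

    def __iter__(self) -> Iterator[CorticalArea]:
        return iter(self.areas)

    def __len__(self) -> int:
        return len(self.areas)

    def __contains__(self, name: str) -> bool:
        return name.strip() in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.areas]

    def resolve(self, name: str) -> CorticalArea:
        """Return the area whose name matches ``name`` exactly after trimming.

        Matching is case-sensitive and never fuzzy; an unknown label raises
        :class:`UnknownAreaError` carrying the three closest known labels.
        """
        key = name.strip() if isinstance(name, str) else ""
        if key not in self._by_name:
            raise UnknownAreaError(name, self._by_name)
        return self._by_name[key]

    def homotopic_of(self, area: CorticalArea | str) -> CorticalArea:
        """Homotopic counterpart of ``area`` in the opposite hemisphere.

        The homotopy relation is the identity on names, hence an involution.
        """
        if isinstance(area, str):
            area = self.resolve(area)
        return self._by_name[area.name]

    def homotopy_target(self, name: str) -> str:
        """Area-level label counted as homotopic for an injection in ``name``.

        For plain areas this is the name itself; for an injection subfield it
        is the subfield's parent area (labeling is charted at area level).
        """
        area = self.resolve(name)
        return area.parent if area.parent is not None else area.name

    def region_of(self, area: CorticalArea | str) -> str:
        if isinstance(area, str):
            area = self.resolve(area)
        return area.region

    # ---- serialization -------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "Parcellation":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "Parcellation":
        areas = [
            CorticalArea(
                name=entry["name"],
                region=entry["region"],
                parent=entry.get("parent"),
                notes=entry.get("notes", ""),
            )
            for entry in payload["areas"]
        ]
        return cls(areas=areas, version=payload.get("version", ""))

    def to_json(self, path: str | Path) -> None:
        entries = []
        for area in self.areas:
            entry: dict = {"name": area.name, "region": area.region}
            if area.parent is not None:
                entry["parent"] = area.parent
            if area.notes:
                entry["notes"] = area.notes
            entries.append(entry)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"version": self.version, "areas": entries}, fh, indent=1)


def default_parcellation() -> Parcellation:
    """The parcellation bundled with the package.

    Covers the prefrontal, premotor, frontal opercular, parietal, cingulate
    and associated labels used by the bundled count fixture, including the
    injection subfield units (e.g. ``"46d (r)"``).
    """
    ref = resources.files("cpnquant.data").joinpath("parcellation.json")
    payload = json.loads(ref.read_text(encoding="utf-8"))
    return Parcellation._from_payload(payload)
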