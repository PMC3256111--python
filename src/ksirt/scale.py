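"""Scale definitions for Likert-type rating instruments.

A :class:`ScaleDefinition` names the items of an instrument, assigns each
item to exactly one subscale, and fixes the common option range (e.g. 1-7
for the PANSS, where 1 = absent and 7 = extreme).  The PANSS 30-item /
3-subscale definition ships as the packaged default (:func:`panss`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class ScaleDefinition:
    """An instrument: ordered items, a subscale partition, and option range.

    Parameters
    ----------
    items
        Ordered list of item IDs (column names of a ratings table).
    subscales
        Mapping subscale name -> ordered list of item IDs.  Every item
        must belong to exactly one subscale.
    option_min, option_max
        Inclusive integer option codes shared by every item.
    labels
        Optional mapping item ID -> human-readable label.
    """

    items: tuple[str, ...]
    subscales: dict[str, tuple[str, ...]]
    option_min: int = 1
    option_max: int = 7
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.option_min >= self.option_max:
            raise ValueError(
                f"option_min ({self.option_min}) must be < option_max ({self.option_max})"
            )
        seen: dict[str, str] = {}
        for name, sub_items in self.subscales.items():
            for it in sub_items:
                if it in seen:
                    raise ValueError(
                        f"item {it!r} in both subscales {seen[it]!r} and {name!r}"
                    )
                if it not in self.items:
                    raise ValueError(f"subscale {name!r} lists unknown item {it!r}")
                seen[it] = name
        missing = [it for it in self.items if it not in seen]
        if missing:
            raise ValueError(f"items not assigned to any subscale: {missing}")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item IDs")

    # -- derived quantities -------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_options(self) -> int:
        return self.option_max - self.option_min + 1

    @property
    def option_codes(self) -> tuple[int, ...]:
        return tuple(range(self.option_min, self.option_max + 1))

    def subscale_of(self, item: str) -> str:
        for name, sub_items in self.subscales.items():
            if item in sub_items:
                return name
        raise KeyError(item)

    def score_range(self, subscale: str | None = None) -> tuple[int, int]:
        """Theoretical summed-score range [J*option_min, J*option_max]."""
        n = len(self.subscales[subscale]) if subscale else self.n_items
        return n * self.option_min, n * self.option_max

    def subset(self, keep: list[str] | tuple[str, ...]) -> "ScaleDefinition":
        """A new definition restricted to ``keep``, preserving subscale grouping
        and item order.  Subscales that lose every item raise ``ValueError``."""
        keep_set = set(keep)
        unknown = keep_set - set(self.items)
        if unknown:
            raise ValueError(f"unknown items: {sorted(unknown)}")
        new_subs: dict[str, tuple[str, ...]] = {}
        for name, sub_items in self.subscales.items():
            kept = tuple(it for it in sub_items if it in keep_set)
            if not kept:
                raise ValueError(f"subscale {name!r} would lose all items")
            new_subs[name] = kept
        return ScaleDefinition(
            items=tuple(it for it in self.items if it in keep_set),
            subscales=new_subs,
            option_min=self.option_min,
            option_max=self.option_max,
            labels={k: v for k, v in self.labels.items() if k in keep_set},
        )

    # -- I/O ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "subscales": {k: list(v) for k, v in self.subscales.items()},
            "option_min": self.option_min,
            "option_max": self.option_max,
            "labels": dict(self.labels),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDefinition":
        return cls(
            items=tuple(d["items"]),
            subscales={k: tuple(v) for k, v in d["subscales"].items()},
            option_min=int(d["option_min"]),
            option_max=int(d["option_max"]),
            labels=dict(d.get("labels", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScaleDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


def panss() -> ScaleDefinition:
    """The packaged PANSS definition: 30 items, subscales Positive (P1-P7),
    Negative (N1-N7) and General (G1-G16), options 1-7."""
    with resources.files("ksirt.fixtures").joinpath("panss_scale.json").open() as fh:
        return ScaleDefinition.from_dict(json.load(fh))
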