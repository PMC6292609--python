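"""Feature catalogues: ordered, categorised lists of canonical feature names.

A catalogue records which features a matrix holds (or should hold), in a fixed
order, each with a category from {local, egonet, regional, centrality,
other_network, external}. Recursive feature names follow the grammar defined
in :mod:`netess.refex`; catalogues are what lets a feature set discovered on
one organism be recomputed identically on every other organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = ("local", "egonet", "regional", "centrality", "other_network", "external")


def recursion_depth(name: str) -> int:
    """Nesting count of sum(...)/mean(...) wrappers; 0 for base features."""
    depth = 0
    while True:
        if name.startswith("sum(") and name.endswith(")"):
            name = name[4:-1]
        elif name.startswith("mean(") and name.endswith(")"):
            name = name[5:-1]
        else:
            return depth
        depth += 1


@dataclass
class FeatureCatalogue:
    """Ordered list of canonical feature names with a category per name."""

    names: list = field(default_factory=list)
    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalogue names must be unique")
        for n in self.names:
            cat = self.categories.get(n)
            if cat is None:
                raise ValueError(f"no category for feature {n!r}")
            if cat not in CATEGORIES:
                raise ValueError(f"invalid category {cat!r} for feature {n!r}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name) -> bool:
        return name in self.categories

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureCatalogue)
            and self.names == other.names
            and self.categories == other.categories
        )

    def subset(self, names) -> "FeatureCatalogue":
        return FeatureCatalogue(list(names), {n: self.categories[n] for n in names})

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for n in self.names:
                fh.write(f"{n}\t{self.categories[n]}\n")

    @classmethod
    def load(cls, path) -> "FeatureCatalogue":
        names, cats = [], {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, cat = line.rstrip("\n").split("\t")
                names.append(name)
                cats[name] = cat
        return cls(names, cats)


def merge(catalogues, dedup: bool = True) -> FeatureCatalogue:
    """Concatenate catalogues preserving first occurrence order; duplicates are
    dropped (first category wins) when ``dedup``."""
    names, cats = [], {}
    for cat in catalogues:
        for n in cat:
            if n in cats:
                if not dedup:
                    raise ValueError(f"duplicate feature {n!r}")
                continue
            names.append(n)
            cats[n] = cat.categories[n]
    return FeatureCatalogue(names, cats)
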