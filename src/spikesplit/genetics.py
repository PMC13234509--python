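"""Mendelian inheritance models for F2 populations.

An F2 population from selfed F1 hybrids segregates 1:2:1 per locus at the
genotype level, which collapses to 3/4 dominant-phenotype (``A_``) and 1/4
recessive (``aa``) under complete dominance.  With independent loci the joint
genotype categories multiply, giving the classical dihybrid and trihybrid
phenotype ratios (3:1, 13:3, 15:1, 61:3, 63:1, ...).  An
:class:`InheritanceModel` names one such genotype-to-phenotype collapse and
carries the two-class ratio it implies; a :class:`RatioLibrary` is the ordered
battery of models an observed split is screened against.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "InheritanceModel",
    "RatioLibrary",
    "ExpectedCounts",
    "f2_genotype_frequencies",
    "phenotype_proportions",
    "expected_counts",
]

#: Per-locus F2 phenotype categories under complete dominance, with the
#: dominant-phenotype category first.  Locus symbols follow the A/B/C
#: convention: ``A_`` means at least one dominant allele, ``aa`` homozygous
#: recessive.
_LOCUS_CATEGORIES = (
    (("A_", Fraction(3, 4)), ("aa", Fraction(1, 4))),
    (("B_", Fraction(3, 4)), ("bb", Fraction(1, 4))),
    (("C_", Fraction(3, 4)), ("cc", Fraction(1, 4))),
)


def f2_genotype_frequencies(n_loci: int) -> dict[str, Fraction]:
    """Exact joint genotype-category frequencies in an F2 population.

    Parameters
    ----------
    n_loci:
        Number of independently segregating loci, 1-3.

    Returns
    -------
    dict
        Mapping from joint category (e.g. ``"A_bb"``) to its exact frequency
        as a :class:`~fractions.Fraction`.  Frequencies sum to 1; each locus
        contributes an independent 3/4 : 1/4 marginal.
    """
    if n_loci not in (1, 2, 3):
        raise ValueError(f"n_loci must be 1, 2 or 3, got {n_loci!r}")
    freqs: dict[str, Fraction] = {}
    for combo in itertools.product(*_LOCUS_CATEGORIES[:n_loci]):
        name = "".join(cat for cat, _ in combo)
        prob = Fraction(1)
        for _, p in combo:
            prob *= p
        freqs[name] = prob
    return freqs


@dataclass(frozen=True)
class InheritanceModel:
    """A named genotype-to-phenotype collapse with its expected F2 ratio.

    Attributes
    ----------
    name:
        Short label, conventionally the ratio string (``"13:3"``).
    n_loci:
        Number of segregating loci (1-3).
    class_map:
        Mapping from every joint genotype category of ``n_loci`` loci to one
        of exactly two phenotype class labels.
    ratio:
        ``(dominant_parts, recessive_parts)`` — the phenotype ratio implied by
        summing F2 genotype frequencies over ``class_map``.  Parts sum to
        ``4 ** n_loci``.
    description:
        Optional free-text mechanism name ("dominant epistasis", ...).
    """

    name: str
    n_loci: int
    class_map: Mapping[str, str]
    ratio: tuple[int, int]
    description: str = ""

    def __post_init__(self) -> None:
        dom, rec = self.ratio
        if dom <= 0 or rec <= 0:
            raise ValueError(f"{self.name}: ratio parts must be positive, got {self.ratio}")
        total = 4**self.n_loci
        if dom + rec != total:
            raise ValueError(
                f"{self.name}: ratio parts must sum to {total} for {self.n_loci} loci, "
                f"got {dom + rec}"
            )
        freqs = f2_genotype_frequencies(self.n_loci)
        if set(self.class_map) != set(freqs):
            missing = set(freqs) - set(self.class_map)
            extra = set(self.class_map) - set(freqs)
            raise ValueError(
                f"{self.name}: class_map must cover every genotype category exactly "
                f"once (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        labels = sorted(set(self.class_map.values()))
        if len(labels) != 2:
            raise ValueError(f"{self.name}: class_map must use exactly two phenotype labels")
        implied = {lab: Fraction(0) for lab in labels}
        for cat, lab in self.class_map.items():
            implied[lab] += freqs[cat]
        if implied[self.dominant_class] != Fraction(dom, total):
            raise ValueError(
                f"{self.name}: class_map implies "
                f"{implied[self.dominant_class] * total}:{implied[self.recessive_class] * total}, "
                f"stored ratio is {dom}:{rec}"
            )

    @property
    def dominant_class(self) -> str:
        """Phenotype label of the majority (dominant) class."""
        freqs = f2_genotype_frequencies(self.n_loci)
        totals: dict[str, Fraction] = {}
        for cat, lab in self.class_map.items():
            totals[lab] = totals.get(lab, Fraction(0)) + freqs[cat]
        return max(totals, key=lambda lab: totals[lab])

    @property
    def recessive_class(self) -> str:
        """Phenotype label of the minority (recessive) class."""
        labels = set(self.class_map.values())
        labels.discard(self.dominant_class)
        return labels.pop()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_loci": self.n_loci,
            "class_map": dict(self.class_map),
            "ratio": list(self.ratio),
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InheritanceModel":
        return cls(
            name=d["name"],
            n_loci=int(d["n_loci"]),
            class_map=dict(d["class_map"]),
            ratio=(int(d["ratio"][0]), int(d["ratio"][1])),
            description=d.get("description", ""),
        )


def phenotype_proportions(model: InheritanceModel) -> tuple[float, float]:
    """Ratio normalized to sum 1, dominant class first."""
    dom, rec = model.ratio
    total = dom + rec
    return dom / total, rec / total


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected class counts for a sample of ``n``, dominant class first."""

    real: tuple[float, float]
    rounded: tuple[int, int]
    n: int


def expected_counts(n: int, model: InheritanceModel) -> ExpectedCounts:
    """Expected dominant/recessive counts under ``model`` for ``n`` plants.

    The real-valued expectations are ``n`` times the phenotype proportions.
    The display rounding rounds the larger class to the nearest integer and
    gives the remainder to the smaller, so both presentations sum exactly to
    ``n`` (e.g. 187 under 3:1 rounds to 140 and 47).  Chi-square testing always
    uses the unrounded expectations.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    p_dom, p_rec = phenotype_proportions(model)
    real = (n * p_dom, n * p_rec)
    major = int(np_floor_half_up(real[0]))
    return ExpectedCounts(real=real, rounded=(major, n - major), n=n)


def np_floor_half_up(x: float) -> int:
    """Round half away from zero (140.25 -> 140, 140.5 -> 141)."""
    import math

    return int(math.floor(x + 0.5))


def _default_models() -> list[InheritanceModel]:
    return [
        InheritanceModel(
            name="3:1",
            n_loci=1,
            class_map={"A_": "dominant", "aa": "recessive"},
            ratio=(3, 1),
            description="monogenic, complete dominance",
        ),
        InheritanceModel(
            name="13:3",
            n_loci=2,
            class_map={"A_B_": "dominant", "A_bb": "dominant", "aabb": "dominant", "aaB_": "recessive"},
            ratio=(13, 3),
            description="dominant epistasis (suppression)",
        ),
        InheritanceModel(
            name="15:1",
            n_loci=2,
            class_map={"A_B_": "dominant", "A_bb": "dominant", "aaB_": "dominant", "aabb": "recessive"},
            ratio=(15, 1),
            description="duplicate dominant genes",
        ),
        InheritanceModel(
            name="61:3",
            n_loci=3,
            class_map={
                cat: ("recessive" if cat == "aabbC_" else "dominant")
                for cat in f2_genotype_frequencies(3)
            },
            ratio=(61, 3),
            description="trigenic epistatic variant",
        ),
        InheritanceModel(
            name="63:1",
            n_loci=3,
            class_map={
                cat: ("recessive" if cat == "aabbcc" else "dominant")
                for cat in f2_genotype_frequencies(3)
            },
            ratio=(63, 1),
            description="triplicate dominant genes",
        ),
    ]


@dataclass
class RatioLibrary:
    """Ordered battery of :class:`InheritanceModel` used for ratio screening.

    The default library carries the five classical two-class F2 ratios
    (3:1, 13:3, 15:1, 61:3, 63:1).  Custom ratios (e.g. 9:7 recessive
    epistasis) can be added programmatically or loaded from a YAML/JSON
    config via :meth:`from_file`.
    """

    entries: list[InheritanceModel] = field(default_factory=_default_models)

    def __post_init__(self) -> None:
        names = [m.name for m in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate model names in library: {names}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> InheritanceModel:
        for m in self.entries:
            if m.name == name:
                return m
        raise KeyError(f"no model named {name!r} in library ({[m.name for m in self.entries]})")

    def subset(self, names: Sequence[str]) -> "RatioLibrary":
        return RatioLibrary(entries=[self.get(n) for n in names])

    def add(self, model: InheritanceModel) -> None:
        if any(m.name == model.name for m in self.entries):
            raise ValueError(f"model {model.name!r} already in library")
        self.entries.append(model)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = {"models": [m.to_dict() for m in self.entries]}
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RatioLibrary":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(entries=[InheritanceModel.from_dict(d) for d in payload["models"]])
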