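"""Rule-of-five filtering, bioactivity classification and drug-score aggregation.

The druglikeness layer consumes a property vector (computed upstream from a
structure, or supplied directly from external property calculators) and
applies three screens:

* **Lipinski rule of five** — MW ≤ 500 Da, logP ≤ 5, HBD ≤ 5, HBA ≤ 10.
  Thresholds are boundary-inclusive: a molecule sitting exactly on a limit
  does not violate it.
* **Veber criteria** — TPSA ≤ 140 Å² and ≤ 10 rotatable bonds.
* **Drug score** — a multiplicative aggregate in (0, 1): each of clogP,
  logS, MW and druglikeness contributes ``½ + ½·s`` with the logistic
  ``s = 1/(1 + exp(a·p + b))``, and each of the four toxicity-risk
  categories multiplies in 1.0 (no risk), 0.8 (medium) or 0.6 (high).

The default logistic parameters are sign-corrected so that the score
*decreases* with growing clogP and MW and *increases* with solubility and
druglikeness — the behaviour of the OSIRIS-style score this reproduces. The
historically printed parameter list (which breaks that monotonicity for logS
and druglikeness) remains available behind ``literal_params=True`` for
comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ToxicityRisk",
    "TOXICITY_CATEGORIES",
    "TOXICITY_MULTIPLIER",
    "MolecularProperties",
    "RuleResult",
    "RuleReport",
    "lipinski_violations",
    "veber_check",
    "BioactivityClass",
    "bioactivity_class",
    "sigmoid_contribution",
    "drug_score",
    "DRUG_SCORE_PARAMS",
    "LITERAL_DRUG_SCORE_PARAMS",
]


class ToxicityRisk(str, enum.Enum):
    NONE = "none"
    MEDIUM = "medium"
    HIGH = "high"


TOXICITY_CATEGORIES = ("mutagenic", "tumorigenic", "irritant", "reproductive")
TOXICITY_MULTIPLIER = {ToxicityRisk.NONE: 1.0, ToxicityRisk.MEDIUM: 0.8, ToxicityRisk.HIGH: 0.6}


def _no_risk() -> dict[str, ToxicityRisk]:
    return {cat: ToxicityRisk.NONE for cat in TOXICITY_CATEGORIES}


@dataclass(frozen=True)
class MolecularProperties:
    """Druglikeness property vector for one molecule.

    ``milogp``/``logs``/``druglikeness`` come from external fragment-based
    predictors and are inputs here, never computed. Counts must be
    non-negative integers; the toxicity map must cover all four categories.
    """

    mw: float | None = None
    milogp: float | None = None
    logs: float | None = None
    tpsa: float | None = None
    nhba: int | None = None
    nhbd: int | None = None
    nrotb: int | None = None
    natoms: int | None = None
    volume: float | None = None
    druglikeness: float | None = None
    toxicity: Mapping[str, ToxicityRisk] = field(default_factory=_no_risk)

    def __post_init__(self):
        for name in ("nhba", "nhbd", "nrotb", "natoms"):
            val = getattr(self, name)
            if val is not None and (val < 0 or int(val) != val):
                raise ValueError(f"{name} must be a non-negative integer, got {val!r}")
        tox = {k: ToxicityRisk(v) for k, v in dict(self.toxicity).items()}
        missing = set(TOXICITY_CATEGORIES) - tox.keys()
        if missing:
            raise ValueError(f"toxicity map missing categories: {sorted(missing)}")
        object.__setattr__(self, "toxicity", tox)

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"required property {name!r} is missing")


@dataclass(frozen=True)
class RuleResult:
    name: str
    threshold: float
    observed: float
    passed: bool


@dataclass(frozen=True)
class RuleReport:
    rules: tuple[RuleResult, ...]

    @property
    def violations(self) -> int:
        return sum(not r.passed for r in self.rules)

    @property
    def passed(self) -> bool:
        return self.violations == 0


_RO5_RULES = (
    ("mw", "MW ≤ 500", 500.0),
    ("milogp", "logP ≤ 5", 5.0),
    ("nhbd", "HBD ≤ 5", 5.0),
    ("nhba", "HBA ≤ 10", 10.0),
)


def lipinski_violations(props: MolecularProperties) -> RuleReport:
    """Evaluate the four rule-of-five criteria (boundary-inclusive)."""
    props.require("mw", "milogp", "nhbd", "nhba")
    results = tuple(
        RuleResult(label, limit, getattr(props, attr), getattr(props, attr) <= limit)
        for attr, label, limit in _RO5_RULES
    )
    return RuleReport(rules=results)


def veber_check(props: MolecularProperties) -> RuleReport:
    """Veber oral-bioavailability criteria: TPSA ≤ 140 Å², ROTB ≤ 10."""
    props.require("tpsa", "nrotb")
    return RuleReport(
        rules=(
            RuleResult("TPSA ≤ 140", 140.0, props.tpsa, props.tpsa <= 140.0),
            RuleResult("ROTB ≤ 10", 10.0, props.nrotb, props.nrotb <= 10.0),
        )
    )


class BioactivityClass(str, enum.Enum):
    CONSIDERABLE = "considerable"
    MODERATE = "moderate"
    INACTIVE = "inactive"


def bioactivity_class(score: float) -> BioactivityClass:
    """Classify a bioactivity score: > 0 considerable, [−0.5, 0] moderate,
    < −0.5 inactive. The boundaries 0 and −0.5 belong to moderate."""
    if not math.isfinite(score):
        raise ValueError("bioactivity score must be finite")
    if score > 0:
        return BioactivityClass.CONSIDERABLE
    if score >= -0.5:
        return BioactivityClass.MODERATE
    return BioactivityClass.INACTIVE


def sigmoid_contribution(p: float, a: float, b: float) -> float:
    """Logistic property contribution ``s = 1/(1 + exp(a·p + b))`` in (0, 1).

    Overflow-safe: extreme arguments saturate at 0 or 1.
    """
    for name, val in (("p", p), ("a", a), ("b", b)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite")
    x = a * p + b
    if x > 700:
        return 0.0
    if x < -700:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


#: sign-corrected logistic (a, b) per property: score falls with clogP and
#: MW, rises with solubility and druglikeness
DRUG_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "milogp": (1.0, -5.0),
    "logs": (-1.0, -5.0),
    "mw": (0.012, -6.0),
    "druglikeness": (-1.0, 0.0),
}

#: the historically printed (a, b) list, kept for comparison only
LITERAL_DRUG_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "milogp": (1.0, -5.0),
    "logs": (1.0, 5.0),
    "mw": (0.012, -6.0),
    "druglikeness": (1.0, 0.0),
}


def drug_score(props: MolecularProperties, literal_params: bool = False) -> float:
    """Aggregate drug score in (0, 1).

    ``DS = Π_i (½ + ½·s_i) · Π_j t_j`` over the four property terms and four
    toxicity multipliers.
    """
    props.require("milogp", "logs", "mw", "druglikeness")
    params = LITERAL_DRUG_SCORE_PARAMS if literal_params else DRUG_SCORE_PARAMS
    score = 1.0
    for name, (a, b) in params.items():
        s = sigmoid_contribution(getattr(props, name), a, b)
        score *= 0.5 + 0.5 * s
    for cat in TOXICITY_CATEGORIES:
        score *= TOXICITY_MULTIPLIER[props.toxicity[cat]]
    return score
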