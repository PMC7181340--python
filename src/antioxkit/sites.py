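"""Multi-criteria identification of the most labile O–H site.

Several independent lines of evidence point at the O–H group that forms the
most stable phenoxyl radical: the lowest bond dissociation enthalpy, the
lowest Wiberg O–H bond order, the lowest pKa, and the most negative charge
on the site oxygen. This module ranks sites on any one metric, measures how
well the metrics agree, and applies the pH rule deciding whether a site is
deprotonated in a given medium (blood pH 7.4 by default).
"""

from __future__ import annotations

import csv
import enum
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .species import normalize_site

__all__ = [
    "SiteEvidence",
    "Direction",
    "DEFAULT_DIRECTIONS",
    "BLOOD_PH",
    "rank_sites",
    "RankedSites",
    "concordance",
    "protonation_state",
    "ProtonationState",
    "ProtonationCall",
    "read_site_evidence",
    "write_site_evidence",
]

#: physiological pH used when none is given
BLOOD_PH = 7.4

_METRICS = ("bde", "bond_order", "atomic_charge", "pka", "de")


@dataclass(frozen=True)
class SiteEvidence:
    """Auxiliary per-site reactivity metrics; at least one must be present.

    ``bond_order`` is the Wiberg index of the O–H bond (dimensionless, must
    lie in (0, 1.5) for a single bond); ``atomic_charge`` is the natural
    charge on the site oxygen in units of e; ``de`` is an opaque
    dissociation-energy ranking metric in kcal/mol.
    """

    site: str
    bde: float | None = None
    bond_order: float | None = None
    atomic_charge: float | None = None
    pka: float | None = None
    de: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "site", normalize_site(self.site))
        if all(getattr(self, m) is None for m in _METRICS):
            raise ValueError(f"site {self.site!r}: at least one metric must be present")
        bo = self.bond_order
        if bo is not None and not (0.0 < bo < 1.5):
            raise ValueError(f"site {self.site!r}: O–H bond order {bo} outside (0, 1.5)")


class Direction(str, enum.Enum):
    ASCENDING = "ascending"
    DESCENDING = "descending"


# Which end of each metric marks the most labile site: lowest BDE, lowest
# bond order, lowest pKa, lowest DE — and the *most negative* oxygen charge
# (numerically smallest), so ascending throughout. The literature's phrase
# "highest charge" refers to magnitude of the negative charge.
DEFAULT_DIRECTIONS: dict[str, Direction] = {m: Direction.ASCENDING for m in _METRICS}


class RankedSites(NamedTuple):
    sites: tuple[str, ...]
    tied: bool


def rank_sites(
    evidence: Sequence[SiteEvidence],
    metric: str,
    direction: Direction | str | None = None,
) -> RankedSites:
    """Order sites by one metric (stable sort; ties keep input order).

    Sites lacking the metric are dropped; the metric must be present for at
    least one site (two for a meaningful ranking, but a single-site table is
    legal and returns that site).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if direction is None:
        direction = DEFAULT_DIRECTIONS[metric]
    direction = Direction(direction)
    scored = [(getattr(e, metric), e.site) for e in evidence if getattr(e, metric) is not None]
    if not scored:
        raise ValueError(f"metric {metric!r} absent for every site")
    reverse = direction is Direction.DESCENDING
    ordered = sorted(scored, key=lambda t: t[0], reverse=reverse)  # timsort: stable
    values = [v for v, _ in scored]
    tied = len(values) != len(set(values))
    return RankedSites(sites=tuple(s for _, s in ordered), tied=tied)


def concordance(
    evidence: Sequence[SiteEvidence],
    metrics: Sequence[str],
    directions: dict[str, Direction] | None = None,
) -> float:
    """Fraction of metrics whose extremal site matches the modal extremal site.

    Each metric nominates the site at its extremal end (per ``directions``,
    default :data:`DEFAULT_DIRECTIONS`); the mode of those nominations is the
    consensus and the returned value is the fraction of metrics agreeing with
    it. 1.0 means every line of evidence points at the same site.
    """
    if not metrics:
        raise ValueError("at least one metric required")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    winners = [rank_sites(evidence, m, directions[m]).sites[0] for m in metrics]
    modal_site, modal_count = Counter(winners).most_common(1)[0]
    return modal_count / len(winners)


class ProtonationState(str, enum.Enum):
    DEPROTONATED = "deprotonated"
    UNDISSOCIATED = "undissociated"


class ProtonationCall(NamedTuple):
    state: ProtonationState
    half_dissociated: bool


def protonation_state(pka: float, ph: float = BLOOD_PH) -> ProtonationCall:
    """Apply the pH rule: a site with pKa below ambient pH is deprotonated.

    At pH = pKa the population is half dissociated; the call reports the
    undissociated state with the ``half_dissociated`` flag set.
    """
    if not (math.isfinite(pka) and math.isfinite(ph)):
        raise ValueError("pka and ph must be finite")
    if ph > pka:
        return ProtonationCall(ProtonationState.DEPROTONATED, False)
    return ProtonationCall(ProtonationState.UNDISSOCIATED, ph == pka)


# ---------------------------------------------------------------------------
# CSV I/O — one row per site, one column per metric, empty cell = absent

_COLUMNS = ("site",) + _METRICS


def read_site_evidence(path: str | Path) -> list[SiteEvidence]:
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if "site" not in (reader.fieldnames or []):
            raise ValueError("site-evidence CSV must carry a 'site' column")
        out = []
        for row in reader:
            kwargs = {"site": (row.get("site") or "").strip()}
            for m in _METRICS:
                raw = (row.get(m) or "").strip()
                kwargs[m] = float(raw) if raw else None
            out.append(SiteEvidence(**kwargs))
    return out


def write_site_evidence(evidence: Iterable[SiteEvidence], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for e in evidence:
            writer.writerow(
                [e.site]
                + ["" if getattr(e, m) is None else repr(getattr(e, m)) for m in _METRICS]
            )
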