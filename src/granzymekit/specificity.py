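"""Rule-based substrate-specificity classification for granzymes.

The primary (P1) substrate preference of a granzyme-family serine protease
is read off a handful of S1-pocket residues in canonical numbering: 189 at
the base of the pocket, 216 and 226 controlling access, and 192 near the
pocket rim.  The default rule cascade (first match wins) is:

1. metase        — Lys192 and Ser216             => P1 Met/Leu
2. aspase        — Asn189, Gly216, Arg226        => P1 Asp
3. trypsin_like  — Asp189, Gly216, Gly226        => P1 Arg/Lys
4. chymase       — Thr/Ala/Ser189, Gly216, Gly226 => P1 Phe/Tyr

The metase rule runs first because Lys192/Ser216 alone identify granzyme M
and must shadow the S1-triplet rules.  Rules are data, not code: the
cascade ships as a YAML file and users can extend it (e.g. for duodenases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .align import NumberingMap
from .io_core import GranzymeKitError, SequenceRecord, _data_path

#: Canonical S1-pocket positions extracted by default.
S1_POSITIONS = (189, 216, 226)
R192 = 192

GROUP_NAMES = ("trypsin_like", "aspase", "chymase", "metase", "unclassified")


class SpecificityError(GranzymeKitError):
    """Invalid specificity-classification input."""


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificityRule:
    """One branch of the classification cascade."""

    rule_id: str
    group: str
    p1: frozenset[str]
    conditions: Mapping[int, frozenset[str]]

    def matches(self, residues: Mapping[int, str | None]) -> bool:
        return all(
            residues.get(pos) in allowed
            for pos, allowed in self.conditions.items()
        )


def load_rules(path: str | None = None) -> tuple[SpecificityRule, ...]:
    """Load the rule cascade from YAML (packaged default when path is None)."""
    with open(path or _data_path("specificity_rules.yaml")) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        rules.append(SpecificityRule(
            rule_id=str(entry["id"]),
            group=str(entry["group"]),
            p1=frozenset(str(x) for x in entry["p1"]),
            conditions={
                int(pos): frozenset(str(r) for r in allowed)
                for pos, allowed in entry["conditions"].items()
            },
        ))
    if not rules:
        raise SpecificityError("rule file contains no rules")
    return tuple(rules)


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificityCall:
    """Extracted key residues plus the enzymatic-group / P1 prediction."""

    query_id: str
    s1_residues: Mapping[int, str | None]
    r192: str | None
    extended_residues: Mapping[int, str | None]
    group: str
    p1: frozenset[str]
    rule_fired: str | None

    def __post_init__(self) -> None:
        if self.group not in GROUP_NAMES:
            raise SpecificityError(f"unknown group {self.group!r}")
        if self.group != "unclassified" and self.rule_fired is None:
            raise SpecificityError("classified call must name the rule fired")
        if (self.group != "unclassified") != bool(self.p1):
            raise SpecificityError("p1 must be non-empty iff classified")

    def summary_row(self) -> dict:
        return {
            "query_id": self.query_id,
            "res189": self.s1_residues.get(189),
            "res192": self.r192,
            "res216": self.s1_residues.get(216),
            "res226": self.s1_residues.get(226),
            "group": self.group,
            "p1": "/".join(sorted(self.p1)) if self.p1 else "",
            "rule_fired": self.rule_fired or "",
        }


def extract_key_residues(mature: SequenceRecord, nmap: NumberingMap,
                         positions: Sequence[int]) -> dict[int, str | None]:
    """Residues at the requested canonical positions (None if unassigned)."""
    return {
        int(pos): nmap.residue_at(mature.residues, int(pos))
        for pos in positions
    }


def classify(residues: Mapping[int, str | None], query_id: str = "",
             rules: Sequence[SpecificityRule] | None = None,
             extended_residues: Mapping[int, str | None] | None = None
             ) -> SpecificityCall:
    """Classify a residue map through the rule cascade (first match wins).

    ``residues`` maps canonical positions to observed residues (None for
    unassigned).  A pure function: the same map always yields the same call.
    """
    rules = rules if rules is not None else load_rules()
    fired = None
    for rule in rules:
        if rule.matches(residues):
            fired = rule
            break
    s1 = {pos: residues.get(pos) for pos in S1_POSITIONS}
    return SpecificityCall(
        query_id=query_id,
        s1_residues=s1,
        r192=residues.get(R192),
        extended_residues=dict(extended_residues or {}),
        group=fired.group if fired else "unclassified",
        p1=fired.p1 if fired else frozenset(),
        rule_fired=fired.rule_id if fired else None,
    )


def classify_sequence(mature: SequenceRecord, nmap: NumberingMap,
                      rules: Sequence[SpecificityRule] | None = None,
                      extended_positions: Sequence[int] = ()) -> SpecificityCall:
    """Extract S1/192 (+ configured extended) residues and classify."""
    positions = set(S1_POSITIONS) | {R192} | set(extended_positions)
    residues = extract_key_residues(mature, nmap, sorted(positions))
    extended = {p: residues[p] for p in extended_positions}
    return classify(residues, query_id=mature.id, rules=rules,
                    extended_residues=extended)


# ---------------------------------------------------------------------------
# Extended-specificity comparison
# ---------------------------------------------------------------------------

def compare_extended(calls: Sequence[SpecificityCall]) -> pd.DataFrame:
    """Tabulate extended (S2/S3) residues across queries.

    All calls must share the same configured extended-position set.  Returns
    a DataFrame with one row per position, one column per query, and a
    boolean ``same`` column flagging positions identical across all queries.
    """
    if len(calls) < 2:
        raise SpecificityError("compare_extended requires >=2 calls")
    position_sets = {frozenset(c.extended_residues) for c in calls}
    if len(position_sets) != 1:
        raise SpecificityError("calls have mismatched extended-position sets")
    positions = sorted(position_sets.pop())
    data = {
        "position": positions,
    }
    for call in calls:
        data[call.query_id] = [call.extended_residues[p] for p in positions]
    df = pd.DataFrame(data)
    query_cols = [c.query_id for c in calls]
    df["same"] = df[query_cols].nunique(axis=1) == 1
    return df
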