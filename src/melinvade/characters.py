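"""Categorical shell-scoring system for *Melanoides* morphs.

Fifteen ordinal shell characters (background colour, colour pattern,
columellar band, general shape, sculpture) scored on small integer scales.
Three characters are conditionally inapplicable: pattern type/size/
heterogeneity (SP, SO, HO) when no colour patterning is present (DO = 0),
band size (SC) when the columellar band is absent (SH = 1), and rib depth
(RD) when axial ribs are absent (RI = 0).  Border cases scored differently
by independent examiners carry two states and are collapsed to their
arithmetic mean for ordination.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NA = None  # sentinel for an inapplicable / missing score

METADATA_COLUMNS = ("specimen_id", "population_code", "species", "clade",
                    "group", "unbleached")


@dataclass(frozen=True)
class NaRule:
    """This character is inapplicable when `other_code` takes a state in `states`."""
    other_code: str
    states: frozenset[int]


@dataclass(frozen=True)
class CharacterDefinition:
    code: str
    description: str
    allowed_states: frozenset[int]
    na_rule: NaRule | None = None

    def __post_init__(self) -> None:
        if not self.allowed_states:
            raise ValueError(f"{self.code}: empty state set")
        if any(s < 0 or s > 5 for s in self.allowed_states):
            raise ValueError(f"{self.code}: states must lie in 0..5")

    @property
    def span(self) -> int:
        return max(self.allowed_states) - min(self.allowed_states)


def canonical_character_set() -> list[CharacterDefinition]:
    """The 15-character shell scoring system (an expanded version of the
    categorical scheme standardly used for Melanoides morphs)."""
    def c(code, desc, lo, hi, na_rule=None):
        return CharacterDefinition(code, desc, frozenset(range(lo, hi + 1)), na_rule)

    do0 = NaRule("DO", frozenset({0}))
    return [
        c("IN", "intensity of the shell background color", 1, 4),
        c("TI", "background tint of the shell", 1, 5),
        c("HE", "heterogeneity of the background color along the whorl", 0, 1),
        c("DO", "overall density of reddish-brown color patterning", 0, 2),
        c("SP", "type of patterning (spots vs. flames)", 0, 3, do0),
        c("SO", "size of the individual spots/flames", 1, 3, do0),
        c("HO", "heterogeneity of color patterning along the whorl", 1, 3, do0),
        c("SH", "presence and sharpness of the columellar band", 1, 3),
        c("SC", "size of the columellar band, when present", 1, 3,
          NaRule("SH", frozenset({1}))),
        c("CO", "conicity of the shell", 1, 3),
        c("RO", "roundness of the body whorl", 1, 3),
        c("GR", "spiral cords/grooves", 0, 3),
        c("CD", "subsutural spiral cord", 0, 3),
        c("RI", "density and width of axial ribs", 0, 3),
        c("RD", "depth of axial ribs, when present", 1, 3,
          NaRule("RI", frozenset({0}))),
    ]


@dataclass
class SpecimenScore:
    specimen_id: str
    population_code: str
    group: str  # native | invasive | unknown
    scores: dict[str, frozenset[int] | None]
    unbleached: bool = False
    extra: dict[str, str] = field(default_factory=dict)


class ValidationError(ValueError):
    """Raised when a score table violates the scoring-system schema."""


@dataclass
class CharacterMatrix:
    definitions: list[CharacterDefinition]
    specimens: list[SpecimenScore]

    @property
    def character_codes(self) -> list[str]:
        return [d.code for d in self.definitions]

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    def validate(self) -> None:
        by_code = {d.code: d for d in self.definitions}
        for rule_holder in self.definitions:
            if rule_holder.na_rule and rule_holder.na_rule.other_code not in by_code:
                raise ValidationError(
                    f"{rule_holder.code}: na_rule references unknown character "
                    f"{rule_holder.na_rule.other_code}")
        seen: set[str] = set()
        for sp in self.specimens:
            if sp.specimen_id in seen:
                raise ValidationError(f"duplicate specimen_id {sp.specimen_id!r}")
            seen.add(sp.specimen_id)
            if set(sp.scores) != set(by_code):
                raise ValidationError(
                    f"{sp.specimen_id}: scored characters do not match the "
                    f"character set")
            for d in self.definitions:
                val = sp.scores[d.code]
                if val is NA:
                    permitted = False
                    if d.na_rule is not None:
                        other = sp.scores[d.na_rule.other_code]
                        if other is not NA and other & d.na_rule.states:
                            permitted = True
                    if not permitted and not sp.unbleached:
                        raise ValidationError(
                            f"{sp.specimen_id}/{d.code}: 'na' not permitted "
                            f"(no applicable na rule and record not flagged "
                            f"unbleached/incomplete)")
                    continue
                if not val:
                    raise ValidationError(f"{sp.specimen_id}/{d.code}: empty score")
                if len(val) > 2:
                    raise ValidationError(
                        f"{sp.specimen_id}/{d.code}: more than 2 states in a "
                        f"border cell")
                bad = val - d.allowed_states
                if bad:
                    raise ValidationError(
                        f"{sp.specimen_id}/{d.code}: state(s) {sorted(bad)} "
                        f"outside allowed range {sorted(d.allowed_states)}")


def _parse_cell(text: str, specimen: str, code: str) -> frozenset[int] | None:
    text = text.strip()
    if text.lower() in ("na", ""):
        return NA
    parts = [p.strip() for p in text.split(",")]
    try:
        states = frozenset(int(p) for p in parts)
    except ValueError:
        raise ValidationError(
            f"{specimen}/{code}: cannot parse cell {text!r}") from None
    if len(parts) != len(states):
        raise ValidationError(f"{specimen}/{code}: repeated state in {text!r}")
    return states


def parse_character_table(path, definitions: Sequence[CharacterDefinition] | None = None,
                          ) -> CharacterMatrix:
    """Read a specimen x character score CSV into a validated CharacterMatrix.

    The CSV carries metadata columns (specimen_id, population_code, group,
    optionally species/clade/unbleached) followed by one column per character
    code.  Cells are "3", "2, 3" (border case), or "na".
    """
    definitions = list(definitions) if definitions else canonical_character_set()
    codes = [d.code for d in definitions]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [h for h in header if h not in METADATA_COLUMNS and h not in codes]
        if unknown:
            raise ValidationError(f"unknown character code(s) in header: {unknown}")
        missing = [c for c in codes if c not in header]
        if missing:
            raise ValidationError(f"character column(s) missing: {missing}")
        specimens = []
        for i, row in enumerate(reader, start=2):
            sid = (row.get("specimen_id") or "").strip()
            if not sid:
                raise ValidationError(f"row {i}: empty specimen_id")
            scores = {c: _parse_cell(row[c], sid, c) for c in codes}
            specimens.append(SpecimenScore(
                specimen_id=sid,
                population_code=(row.get("population_code") or sid).strip(),
                group=(row.get("group") or "unknown").strip(),
                scores=scores,
                unbleached=(row.get("unbleached") or "0").strip() in ("1", "true", "yes"),
                extra={k: v for k, v in row.items()
                       if k in ("species", "clade") and v is not None},
            ))
    matrix = CharacterMatrix(definitions, specimens)
    matrix.validate()
    return matrix


def load_melanoides_scores() -> CharacterMatrix:
    """The shipped transcription of the published Melanoides score table."""
    with resources.as_file(resources.files("melinvade.data") /
                           "melanoides_shell_scores.csv") as p:
        return parse_character_table(p)


def collapse_multistate(matrix: CharacterMatrix) -> pd.DataFrame:
    """Numeric score matrix: border cells become arithmetic means, na -> NaN.

    Returns a specimens x characters DataFrame indexed by specimen_id.
    """
    matrix.validate()
    codes = matrix.character_codes
    data = np.full((len(matrix.specimens), len(codes)), np.nan)
    for i, sp in enumerate(matrix.specimens):
        for j, code in enumerate(codes):
            val = sp.scores[code]
            if val is not NA:
                data[i, j] = float(np.mean(sorted(val)))
    return pd.DataFrame(data, index=pd.Index(matrix.specimen_ids, name="specimen_id"),
                        columns=codes)


def group_map(matrix: CharacterMatrix) -> dict[str, str]:
    return {s.specimen_id: s.group for s in matrix.specimens}


def write_character_table(matrix: CharacterMatrix, path) -> None:
    """Write a CharacterMatrix back to the score-table CSV format."""
    codes = matrix.character_codes
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "population_code", "group", "unbleached"]
                   + codes)
        for sp in matrix.specimens:
            row = [sp.specimen_id, sp.population_code, sp.group,
                   "1" if sp.unbleached else "0"]
            for c in codes:
                val = sp.scores[c]
                if val is NA:
                    row.append("na")
                else:
                    row.append(", ".join(str(s) for s in sorted(val)))
            w.writerow(row)
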