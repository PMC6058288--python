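"""Plaque-assay lysis profiles and knockout-vs-wild-type concordance.

A strain's lysis profile over a phage panel is recorded on an ordinal
scale: 0 = full resistance ('-'), 1 = partial lysis ('(+)'),
2 = full lysis ('+'), optionally refined by the dilution depth (index of
the most dilute spot still cleared in a spot-dilution series).

Knockout phenotypes are compared to the wild type per phage, with
directionality: a knockout of a screen-called resistance gene is predicted
to show increased lysis, a susceptibility-gene knockout decreased lysis.
Phages for which the wild type is already at the scale's ceiling (or
floor) cannot reveal a further increase (or decrease) and are flagged
unobservable in that direction and excluded from the agreement denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .consensus import RESISTANCE, SUSCEPTIBILITY

__all__ = [
    "FULL_RESISTANCE",
    "PARTIAL_LYSIS",
    "FULL_LYSIS",
    "GRADE_TOKENS",
    "LysisProfile",
    "ProfileChange",
    "grade_lysis",
    "dilution_depth",
    "compare_profiles",
    "prediction_from_class",
    "concordance",
    "profiles_to_tsv",
    "profiles_from_tsv",
]

FULL_RESISTANCE = 0
PARTIAL_LYSIS = 1
FULL_LYSIS = 2

GRADE_TOKENS = {"-": FULL_RESISTANCE, "(+)": PARTIAL_LYSIS, "+": FULL_LYSIS}
_TOKEN_OF = {v: k for k, v in GRADE_TOKENS.items()}

INCREASED = "increased"
DECREASED = "decreased"
NO_CHANGE = "no_change"

INCREASED_LYSIS = "increased_lysis"
DECREASED_LYSIS = "decreased_lysis"


@dataclass
class LysisProfile:
    """Ordinal lysis grades of one strain across a phage panel."""

    strain_id: str
    grades: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for phage, g in self.grades.items():
            if g not in (FULL_RESISTANCE, PARTIAL_LYSIS, FULL_LYSIS):
                raise ValueError(f"grade {g} for {phage} outside ordinal scale")

    @property
    def panel(self) -> frozenset[str]:
        return frozenset(self.grades)


def grade_lysis(spot_series: Sequence[bool], reference_depth: int | None = None) -> int:
    """Grade a spot-dilution series ordered from undiluted to most dilute.

    Full lysis (2) requires clearing at every spot up to the panel's
    reference depth (default: the whole series); full resistance (0) means
    no spot cleared; anything else is partial (1).
    """
    spots = list(spot_series)
    if not spots:
        raise ValueError("empty spot series")
    depth = len(spots) if reference_depth is None else reference_depth
    if not 1 <= depth <= len(spots):
        raise ValueError("reference_depth outside series")
    if not any(spots):
        return FULL_RESISTANCE
    if all(spots[:depth]):
        return FULL_LYSIS
    return PARTIAL_LYSIS


def dilution_depth(spot_series: Sequence[bool]) -> int:
    """Index of the most dilute spot still cleared; -1 if none cleared."""
    spots = list(spot_series)
    if not spots:
        raise ValueError("empty spot series")
    cleared = [i for i, s in enumerate(spots) if s]
    return cleared[-1] if cleared else -1


@dataclass(frozen=True)
class ProfileChange:
    """Direction of a knockout's lysis change for one phage.

    ``unobservable_up``/``unobservable_down`` flag phages where the wild
    type already sits at the ceiling/floor of the scale, so a change in
    that direction could not have been seen on a plate.
    """

    direction: str  # INCREASED / DECREASED / NO_CHANGE
    unobservable_up: bool = False
    unobservable_down: bool = False


def compare_profiles(wt: LysisProfile, ko: LysisProfile) -> dict[str, ProfileChange]:
    """Per-phage ordinal comparison of a knockout against the wild type."""
    if wt.panel != ko.panel:
        raise ValueError("wild-type and knockout phage panels differ")
    changes: dict[str, ProfileChange] = {}
    for phage in sorted(wt.grades):
        w, k = wt.grades[phage], ko.grades[phage]
        if k > w:
            direction = INCREASED
        elif k < w:
            direction = DECREASED
        else:
            direction = NO_CHANGE
        changes[phage] = ProfileChange(
            direction=direction,
            unobservable_up=w == FULL_LYSIS,
            unobservable_down=w == FULL_RESISTANCE,
        )
    return changes


def prediction_from_class(tradis_class: str) -> str:
    """Predicted knockout phenotype from the screen's gene class.

    Knocking out a resistance gene removes a brake on the phage:
    increased lysis.  Knocking out a susceptibility gene removes something
    the phage exploits: decreased lysis.
    """
    if tradis_class == RESISTANCE:
        return INCREASED_LYSIS
    if tradis_class == SUSCEPTIBILITY:
        return DECREASED_LYSIS
    raise ValueError(f"no phenotype prediction for class {tradis_class!r}")


def concordance(
    predictions: Mapping[str, str],
    changes: Mapping[str, Mapping[str, ProfileChange]],
) -> pd.DataFrame:
    """Score observed knockout changes against predicted directions.

    For each knockout, each panel phage contributes exactly one of: agree
    (observed direction matches the prediction), oppose (opposite
    direction), unobservable (no change where the wild type's grade made
    the predicted direction impossible to see), or no_change.
    """
    rows = []
    for knockout, phage_changes in changes.items():
        if knockout not in predictions:
            raise ValueError(f"no prediction for knockout {knockout!r}")
        predicted = predictions[knockout]
        if predicted not in (INCREASED_LYSIS, DECREASED_LYSIS):
            raise ValueError(f"invalid prediction {predicted!r}")
        want = INCREASED if predicted == INCREASED_LYSIS else DECREASED
        n_agree = n_oppose = n_none = n_unobs = 0
        for change in phage_changes.values():
            if change.direction == NO_CHANGE:
                blocked = (
                    change.unobservable_up
                    if want == INCREASED
                    else change.unobservable_down
                )
                if blocked:
                    n_unobs += 1
                else:
                    n_none += 1
            elif change.direction == want:
                n_agree += 1
            else:
                n_oppose += 1
        rows.append(
            {
                "knockout": knockout,
                "prediction": predicted,
                "n_agree": n_agree,
                "n_oppose": n_oppose,
                "n_no_change": n_none,
                "n_unobservable": n_unobs,
            }
        )
    return pd.DataFrame(rows)


def profiles_to_tsv(profiles: Sequence[LysisProfile], path: str | Path) -> None:
    """Write a strain x phage grid of {+, (+), -} tokens."""
    panel = sorted(profiles[0].panel) if profiles else []
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(panel) + "\n")
        for p in profiles:
            if sorted(p.panel) != panel:
                raise ValueError("profiles cover different phage panels")
            fh.write(p.strain_id + "\t" + "\t".join(_TOKEN_OF[p.grades[x]] for x in panel) + "\n")


def profiles_from_tsv(path: str | Path) -> list[LysisProfile]:
    """Read a strain x phage grid of tokens or integer grades."""
    profiles = []
    with open(path) as fh:
        panel = fh.readline().rstrip("\n").split("\t")[1:]
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            grades = {}
            for phage, cell in zip(panel, cells[1:]):
                grades[phage] = GRADE_TOKENS[cell] if cell in GRADE_TOKENS else int(cell)
            profiles.append(LysisProfile(strain_id=cells[0], grades=grades))
    return profiles
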