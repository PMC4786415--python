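"""Periodicity algebra for coiled-coil repeat patterns.

A coiled-coil repeat that accommodates ``r`` residues in ``t`` helical turns
has a local periodicity of ``r/t`` residues per turn, measured relative to
the bundle axis.  An unperturbed α-helix has a periodicity of about 3.63
residues per turn; repeats below that value supercoil left-handed (the
heptad, 7/2 = 3.5), repeats above it right-handed (the hendecad, 11/3 ≈
3.67).  Supercoiling strains the constituent helices, which bounds the
periodicities a coiled coil can actually assume: 10/3 ≈ 3.33 (the stammer)
marks the lower edge, and by symmetry around 3.63 the upper limit is
expected near 3.9.

Insertions of 1–6 residues into the heptad background can be delocalized
over one or more neighbouring heptads; each choice of delocalization and
added helical turns yields a rational periodicity.  Insertions of 2 or 6
residues have no accessible accommodation at moderate delocalization —
these are the cases resolved structurally by β-layer formation instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

#: Periodicity of the unperturbed, straight α-helix (residues per turn).
REFERENCE_PERIODICITY = 3.63

#: Band of periodicities accessible to α-helical coiled coils, inclusive.
#: The lower limit is the stammer periodicity 10/3; the upper limit mirrors
#: the ~0.3 residues/turn strain margin on the right-handed side.
ACCESSIBLE_BAND: tuple[Fraction, Fraction] = (Fraction(10, 3), Fraction(39, 10))

Handedness = Literal["left", "right", "none"]


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat pattern of ``residues`` residues over ``turns`` helical turns."""

    residues: int
    turns: int

    def __post_init__(self) -> None:
        if self.residues < 1 or self.turns < 1:
            raise ValueError("residues and turns must be positive integers")

    @property
    def periodicity(self) -> Fraction:
        """Exact periodicity in residues per turn."""
        return Fraction(self.residues, self.turns)

    @property
    def periodicity_value(self) -> float:
        return float(self.periodicity)

    @property
    def handedness(self) -> Handedness:
        p = float(self.periodicity)
        if p < REFERENCE_PERIODICITY:
            return "left"
        if p > REFERENCE_PERIODICITY:
            return "right"
        return "none"

    @property
    def accessible(self) -> bool:
        lo, hi = ACCESSIBLE_BAND
        return lo <= self.periodicity <= hi

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.residues}/{self.turns} = {self.periodicity_value:.2f} "
            f"({self.handedness}-handed, "
            f"{'accessible' if self.accessible else 'inaccessible'})"
        )


def periodicity(residues: int, turns: int) -> RepeatSpec:
    """Periodicity of a repeat of ``residues`` residues over ``turns`` turns.

    Examples
    --------
    >>> periodicity(7, 2).periodicity_value
    3.5
    >>> periodicity(11, 3).handedness
    'right'
    """
    return RepeatSpec(residues, turns)


@dataclass(frozen=True)
class InsertionSpec:
    """An insertion of 1–6 residues delocalized over whole heptads.

    The insertion extends ``heptads_delocalized`` background heptads
    (7 residues / 2 turns each) by ``insert_length`` residues, accommodated
    in ``2 * heptads_delocalized + added_turns`` helical turns.
    """

    insert_length: int
    heptads_delocalized: int
    added_turns: int

    def __post_init__(self) -> None:
        if not 1 <= self.insert_length <= 6:
            raise ValueError("insert_length must be in 1..6")
        if self.heptads_delocalized < 1:
            raise ValueError("heptads_delocalized must be >= 1")

    @property
    def total_residues(self) -> int:
        return 7 * self.heptads_delocalized + self.insert_length

    @property
    def total_turns(self) -> int:
        return 2 * self.heptads_delocalized + self.added_turns

    @property
    def repeat(self) -> RepeatSpec:
        return RepeatSpec(self.total_residues, self.total_turns)


def insertion_periodicity(
    insert_length: int,
    heptads: int,
    added_turns: int | Literal["optimal"] = "optimal",
) -> RepeatSpec:
    """Periodicity of an insertion delocalized over ``heptads`` heptads.

    With ``added_turns="optimal"`` the integer number of extra helical
    turns is chosen to bring the periodicity closest to the unperturbed
    3.63 residues/turn; ties break toward the lower periodicity, matching
    the left-handed bias of the heptad background.

    Examples
    --------
    >>> insertion_periodicity(4, 1).periodicity
    Fraction(11, 3)
    >>> insertion_periodicity(5, 2).periodicity_value
    3.8
    """
    if added_turns == "optimal":
        added_turns = _optimal_added_turns(insert_length, heptads)
    spec = InsertionSpec(insert_length, heptads, int(added_turns))
    return spec.repeat


def _optimal_added_turns(insert_length: int, heptads: int) -> int:
    residues = 7 * heptads + insert_length
    best: tuple[float, float, int] | None = None
    # Any optimum lies within a few turns of residues/3.63; scan generously.
    for added in range(-2 * heptads + 1, 2 * heptads + insert_length + 1):
        turns = 2 * heptads + added
        if turns < 1:
            continue
        p = residues / turns
        key = (abs(p - REFERENCE_PERIODICITY), p, added)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2]


@dataclass(frozen=True)
class AccommodationRow:
    heptads_delocalized: int
    repeat: RepeatSpec


@dataclass(frozen=True)
class AccommodationReport:
    """Optimal accommodation of an insertion per delocalization level."""

    insert_length: int
    rows: Sequence[AccommodationRow]
    #: True when no delocalization up to ``beta_layer_horizon`` heptads
    #: yields an accessible periodicity — the regime where the insertion
    #: is resolved by β-layer formation rather than by supercoiling.
    requires_beta_layer: bool
    beta_layer_horizon: int


def accommodation_report(
    insert_length: int,
    max_heptads: int = 2,
    beta_layer_horizon: int = 2,
) -> AccommodationReport:
    """Tabulate optimal accommodations of an insertion per delocalization.

    For every delocalization 1..``max_heptads`` the optimal-turn repeat is
    listed with its accessibility.  The ``requires_beta_layer`` flag is set
    when no delocalization up to ``beta_layer_horizon`` heptads reaches the
    accessible band.
    """
    if max_heptads < 1:
        raise ValueError("max_heptads must be >= 1")
    rows = [
        AccommodationRow(h, insertion_periodicity(insert_length, h, "optimal"))
        for h in range(1, max_heptads + 1)
    ]
    horizon = min(beta_layer_horizon, max_heptads)
    requires = not any(r.repeat.accessible for r in rows[:horizon])
    return AccommodationReport(insert_length, rows, requires, horizon)
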