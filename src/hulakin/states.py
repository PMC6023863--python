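"""State space of a four-state photoswitch with a chiral axis.

The chromophore carries a central C=C double bond (configuration Z or E)
and an adjacent chiral axis with two atropisomeric settings.  The four
thermally stable diastereomers are labelled A-D:

    A = (Z, ax1)    B = (Z, ax2)    C = (E, ax1)    D = (E, ax2)

``ax1``/``ax2`` are abstract labels for the two axial chiralities; the
absolute P/M (or R/S) assignment plays no role in any computation.  With
this assignment a photoreaction that flips

* only the axis is a single-bond rotation (SBR): A<->B, C<->D;
* only the double bond is a double-bond isomerization (DBI): A<->C, B<->D;
* both at once is a hula twist (HT): A<->D, B<->C.

The fixed alphabetical order A < B < C < D defines row/column index order
(0..3) in every matrix used elsewhere in the package.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, NamedTuple

from .errors import ValidationError

__all__ = [
    "Isomer",
    "ISOMERS",
    "DoubleBond",
    "Axis",
    "StereoDescriptor",
    "Motion",
    "as_isomer",
    "stereo_of",
    "classify_motion",
    "motion_partner",
]


class Isomer(str, Enum):
    """One of the four diastereomeric states, ordered A < B < C < D."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def index(self) -> int:
        """Row/column index (0..3) in matrix types."""
        return "ABCD".index(self.value)

    def __lt__(self, other: "Isomer") -> bool:  # total order for sorting
        if isinstance(other, Isomer):
            return self.index < other.index
        return NotImplemented


ISOMERS: tuple[Isomer, ...] = (Isomer.A, Isomer.B, Isomer.C, Isomer.D)


class DoubleBond(str, Enum):
    Z = "Z"
    E = "E"


class Axis(str, Enum):
    AX1 = "ax1"
    AX2 = "ax2"


class StereoDescriptor(NamedTuple):
    """Z/E configuration of the double bond plus the axial-chirality label."""

    double_bond: DoubleBond
    axis: Axis


_STEREO: dict[Isomer, StereoDescriptor] = {
    Isomer.A: StereoDescriptor(DoubleBond.Z, Axis.AX1),
    Isomer.B: StereoDescriptor(DoubleBond.Z, Axis.AX2),
    Isomer.C: StereoDescriptor(DoubleBond.E, Axis.AX1),
    Isomer.D: StereoDescriptor(DoubleBond.E, Axis.AX2),
}


class Motion(str, Enum):
    """Geometric type of a state-to-state photoreaction."""

    SBR = "SBR"  # single-bond rotation: axis flips, double bond kept
    DBI = "DBI"  # double-bond isomerization: Z/E flips, axis kept
    HT = "HT"    # hula twist: both flip in one photoreaction
    NONE = "NONE"  # identity (no transition)


def as_isomer(label: "Isomer | str") -> Isomer:
    """Coerce a label to :class:`Isomer`, raising ``ValidationError`` if unknown."""
    if isinstance(label, Isomer):
        return label
    try:
        return Isomer(str(label).strip().upper())
    except ValueError:
        raise ValidationError(
            f"unknown isomer label {label!r}; expected one of A, B, C, D"
        ) from None


def stereo_of(label: "Isomer | str") -> StereoDescriptor:
    """Return the (double bond, axis) stereodescriptor pair of an isomer."""
    return _STEREO[as_isomer(label)]


def classify_motion(src: "Isomer | str", dst: "Isomer | str") -> Motion:
    """Classify the photoreaction taking ``src`` to ``dst``.

    The classification compares stereodescriptors, so it is symmetric:
    ``classify_motion(x, y) == classify_motion(y, x)``.
    """
    s, d = stereo_of(src), stereo_of(dst)
    bond_flip = s.double_bond != d.double_bond
    axis_flip = s.axis != d.axis
    if not bond_flip and not axis_flip:
        return Motion.NONE
    if bond_flip and axis_flip:
        return Motion.HT
    return Motion.DBI if bond_flip else Motion.SBR


def motion_partner(src: "Isomer | str", motion: Motion) -> Isomer:
    """Return the unique target reached from ``src`` by the given motion."""
    src = as_isomer(src)
    if motion is Motion.NONE:
        return src
    for dst in ISOMERS:
        if dst is not src and classify_motion(src, dst) is motion:
            return dst
    raise ValidationError(f"no partner for motion {motion!r}")  # pragma: no cover


def targets_by_motion(src: "Isomer | str") -> dict[Motion, Isomer]:
    """Map each proper motion type to its target from ``src``."""
    src = as_isomer(src)
    return {m: motion_partner(src, m) for m in (Motion.SBR, Motion.DBI, Motion.HT)}


def indices(labels: Iterable["Isomer | str"]) -> list[int]:
    """Matrix indices of a sequence of labels."""
    return [as_isomer(x).index for x in labels]
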