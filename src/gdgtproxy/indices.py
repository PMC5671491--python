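"""Proxy indices derived from a single isoprenoid GDGT distribution.

All functions take a :class:`~gdgtproxy.dataset.GDGTProfile` with
fractional abundances in percent.  Because every index except the ring
indices is a ratio of abundances, they are invariant to the profile's
overall scale; the ring indices divide by 100 and therefore presume a
normalized (percent) profile.

A ratio whose denominator is zero is *undefined* and returned as NaN — an
explicit marker that propagates through screening and statistics rather
than raising, because field datasets legitimately contain, e.g., zero
crenarchaeol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dataset import BrGDGTProfile, GDGTProfile

__all__ = [
    "IndexSet",
    "tex86",
    "ring_index_1",
    "ring_index_2",
    "methane_index",
    "pct_gdgt2",
    "simple_ratios",
    "bit_index",
    "compute_index_set",
    "UNDEFINED",
]

#: Marker for an index whose denominator is zero.
UNDEFINED = math.nan


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


@dataclass(frozen=True)
class IndexSet:
    """All proxy indices for one GDGT profile.

    Any field may be NaN (undefined) when its denominator is zero; ``bit``
    is NaN whenever no branched-GDGT data were supplied.
    """

    tex86: float = math.nan
    ri1: float = math.nan
    ri2: float = math.nan
    methane_index: float = math.nan
    pct_gdgt2: float = math.nan
    ratio_2_3: float = math.nan
    ratio_0_cren: float = math.nan
    ratio_2_cren: float = math.nan
    bit: float = math.nan

    def defined(self, name: str) -> bool:
        return not math.isnan(getattr(self, name))


def tex86(p: GDGTProfile) -> float:
    """TetraEther indeX of 86 carbons.

    ([GDGT-2] + [GDGT-3] + [Cren']) /
    ([GDGT-1] + [GDGT-2] + [GDGT-3] + [Cren']), in [0, 1].
    """
    num = p.g2 + p.g3 + p.cren_iso
    return _ratio(num, p.g1 + num)


def ring_index_1(p: GDGTProfile) -> float:
    """Weighted-average cyclopentane ring number, crenarchaeol variant.

    ([GDGT-1] + 2[GDGT-2] + 3[GDGT-3] + 4[Cren] + 4[Cren'])/100, counting
    crenarchaeol and its regioisomer with weight 4; GDGT-4 is not a term.
    This is the variant the global core-top RI-TEX86 calibration uses.
    """
    return (p.g1 + 2 * p.g2 + 3 * p.g3 + 4 * p.cren + 4 * p.cren_iso) / 100.0


def ring_index_2(p: GDGTProfile) -> float:
    """Ring index with crenarchaeol replaced by GDGT-4.

    ([GDGT-1] + 2[GDGT-2] + 3[GDGT-3] + 4[GDGT-4] + 4[Cren'])/100.
    Dropping crenarchaeol removes the dominant thaumarchaeotal biomarker
    from the weighting, making the index sensitive to cyclopentane-ring
    GDGTs from other archaea (e.g. MG-II Euryarchaeota).
    """
    return (p.g1 + 2 * p.g2 + 3 * p.g3 + 4 * p.g4 + 4 * p.cren_iso) / 100.0


def methane_index(p: GDGTProfile) -> float:
    """Methane Index: ([1]+[2]+[3]) / ([1]+[2]+[3]+[Cren]+[Cren']).

    High values (> 0.5) indicate methanotrophic archaeal input.
    """
    num = p.g1 + p.g2 + p.g3
    return _ratio(num, num + p.cren + p.cren_iso)


def pct_gdgt2(p: GDGTProfile) -> float:
    """%GDGT-2 = 100 * [GDGT-2] / ([GDGT-1] + [GDGT-2] + [GDGT-3]).

    The screening literature states only the threshold (> 45), not the
    denominator; this implementation uses GDGTs 1-3 (no crenarchaeol
    regioisomer) and isolates the definition here so it can be swapped.
    """
    den = p.g1 + p.g2 + p.g3
    return _ratio(100.0 * p.g2, den)


def simple_ratios(p: GDGTProfile) -> tuple[float, float, float]:
    """(GDGT-2/GDGT-3, GDGT-0/Cren, GDGT-2/Cren); NaN on zero denominators."""
    return (
        _ratio(p.g2, p.g3),
        _ratio(p.g0, p.cren),
        _ratio(p.g2, p.cren),
    )


def bit_index(p: GDGTProfile, b: BrGDGTProfile) -> float:
    """Branched and Isoprenoid Tetraether index.

    (Ia + IIa + IIIa) / (Ia + IIa + IIIa + [Cren]), in [0, 1]; high values
    (> 0.2) indicate terrestrial/soil GDGT input.  Branched and isoprenoid
    abundances must be on a common response scale (caller's
    responsibility).
    """
    br = b.total()
    return _ratio(br, br + p.cren)


def compute_index_set(p: GDGTProfile, b: BrGDGTProfile | None = None) -> IndexSet:
    """Compute every index for one profile; undefined entries become NaN."""
    r23, r0c, r2c = simple_ratios(p)
    return IndexSet(
        tex86=tex86(p),
        ri1=ring_index_1(p),
        ri2=ring_index_2(p),
        methane_index=methane_index(p),
        pct_gdgt2=pct_gdgt2(p),
        ratio_2_3=r23,
        ratio_0_cren=r0c,
        ratio_2_cren=r2c,
        bit=bit_index(p, b) if b is not None else UNDEFINED,
    )
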