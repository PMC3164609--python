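"""Theoretical fragment-ion generation for CID ion-trap spectra.

For a modified peptide at a given precursor charge this module predicts:

* the primary b/y backbone ladders at fragment charges 1..max,
* −H3PO4 satellites for every fragment carrying phospho-Ser/Thr
  (beta-elimination of phosphoric acid; phospho-Tyr does not eliminate),
* optional −H2O/−NH3 satellites,
* the precursor ion and its −H3PO4 neutral-loss product,
* the phospho-Tyr immonium marker when the peptide carries phospho-Tyr,
* dehydro-residue ladders: the peptide after phosphate loss, with
  phospho-Ser → dehydroalanine and phospho-Thr → dehydro-2-aminobutyric
  acid (residue − water), as seen in MS3/MSA scans.

a/c/z ions are deliberately absent: this models CID, not ETD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .masschem import (
    CO,
    H3PO4,
    PROTON,
    PTYR_IMMONIUM_MZ,
    RESIDUE_MASSES,
    WATER,
    ModifiedPeptide,
    peptide_neutral_mass,
)

__all__ = ["TheoreticalIon", "ion_series", "dehydro_ion_series",
           "hypothesis_ion_set", "fragment_spans"]

# Loss-state labels.
LOSS_NONE = "none"
LOSS_H3PO4 = "minus_H3PO4"
LOSS_H2O = "minus_H2O"
LOSS_NH3 = "minus_NH3"

NH3 = 17.026549

_H2O_CAPABLE = set("STED")
_NH3_CAPABLE = set("RKNQ")


@dataclass(frozen=True)
class TheoreticalIon:
    """One predicted fragment with its m/z.

    ``index`` is the cleavage position (b_i / y_i); 0 for precursor and
    immonium ions. ``carries_phospho`` refers to phospho-S/T within the
    fragment (the beta-elimination-capable payload); ``contains_dehydro``
    marks fragments from the phosphate-lost (dehydro) ladder.
    """

    series: str  # "b" | "y" | "precursor" | "immonium"
    index: int
    charge: int
    loss_state: str
    mz: float
    carries_phospho: bool = False
    contains_dehydro: bool = False

    @property
    def label(self) -> str:
        if self.series == "precursor":
            core = f"[M+{self.charge}H]"
        elif self.series == "immonium":
            core = "imm"
        else:
            core = f"{self.series}{self.index}"
        z = f"({self.charge}+)" if self.series != "precursor" else f"{self.charge}+"
        tag = {LOSS_NONE: "", LOSS_H3PO4: "-H3PO4", LOSS_H2O: "-H2O",
               LOSS_NH3: "-NH3"}[self.loss_state]
        dh = "~" if self.contains_dehydro else ""
        return f"{dh}{core}{tag}{z}"

    def key(self) -> tuple:
        """Identity of the ion ignoring m/z — used to pair ions across
        phospho-isoforms when hunting site-determining evidence."""
        return (self.series, self.index, self.charge, self.loss_state,
                self.contains_dehydro)


def _position_masses(
    pep: ModifiedPeptide, dehydro_sites: frozenset[int]
) -> list[float]:
    """Residue mass at each 1-based position, mods folded in.

    Dehydro sites lose their phospho mod and one water (beta-elimination).
    Terminal mods are folded into the first/last residue.
    """
    masses = [RESIDUE_MASSES[ch] for ch in pep.sequence]
    for pos, spec in pep.mods:
        if pos == "N-term":
            masses[0] += spec.delta_mass
        elif pos == "C-term":
            masses[-1] += spec.delta_mass
        elif pos in dehydro_sites:
            continue  # phospho gone with the H3PO4
        else:
            masses[pos - 1] += spec.delta_mass
    for pos in dehydro_sites:
        masses[pos - 1] -= WATER
    return masses


def _series_ions(
    pep: ModifiedPeptide,
    max_fragment_charge: int,
    losses: frozenset[str],
    dehydro_sites: frozenset[int],
    precursor_charge: int | None,
) -> list[TheoreticalIon]:
    n = len(pep.sequence)
    pm = _position_masses(pep, dehydro_sites)
    phospho_st = set(pep.phospho_st_positions) - dehydro_sites
    is_dehydro = bool(dehydro_sites)

    # H2O/NH3 capability per prefix/suffix.
    seq = pep.sequence
    out: list[TheoreticalIon] = []

    def emit(series: str, idx: int, neutral: float, carries: bool,
             dehydro: bool, can_h2o: bool, can_nh3: bool) -> None:
        for z in range(1, max_fragment_charge + 1):
            mz = (neutral + z * PROTON) / z
            out.append(TheoreticalIon(series, idx, z, LOSS_NONE, mz,
                                      carries, dehydro))
            if carries:
                out.append(TheoreticalIon(series, idx, z, LOSS_H3PO4,
                                          mz - H3PO4 / z, carries, dehydro))
            if LOSS_H2O in losses and can_h2o:
                out.append(TheoreticalIon(series, idx, z, LOSS_H2O,
                                          mz - WATER / z, carries, dehydro))
            if LOSS_NH3 in losses and can_nh3:
                out.append(TheoreticalIon(series, idx, z, LOSS_NH3,
                                          mz - NH3 / z, carries, dehydro))

    prefix = 0.0
    for i in range(1, n):  # b1..b(n-1)
        prefix += pm[i - 1]
        frag = seq[:i]
        emit("b", i, prefix, any(p <= i for p in phospho_st),
             is_dehydro and any(p <= i for p in dehydro_sites),
             bool(set(frag) & _H2O_CAPABLE), bool(set(frag) & _NH3_CAPABLE))

    suffix = 0.0
    for i in range(1, n):  # y1..y(n-1)
        suffix += pm[n - i]
        frag = seq[n - i:]
        emit("y", i, suffix + WATER, any(p > n - i for p in phospho_st),
             is_dehydro and any(p > n - i for p in dehydro_sites),
             bool(set(frag) & _H2O_CAPABLE), bool(set(frag) & _NH3_CAPABLE))

    if precursor_charge is not None:
        neutral = sum(pm) + WATER
        z = precursor_charge
        mz = (neutral + z * PROTON) / z
        carries = bool(phospho_st)
        out.append(TheoreticalIon("precursor", 0, z, LOSS_NONE, mz, carries,
                                  is_dehydro))
        if carries:
            out.append(TheoreticalIon("precursor", 0, z, LOSS_H3PO4,
                                      mz - H3PO4 / z, carries, is_dehydro))
    return out


def ion_series(
    pep: ModifiedPeptide,
    max_fragment_charge: int = 1,
    losses: Iterable[str] = (),
    precursor_charge: int | None = None,
) -> list[TheoreticalIon]:
    """Complete theoretical ion set for a modified peptide.

    b1..b(n−1) and y1..y(n−1) at charges 1..max_fragment_charge, with a
    −H3PO4 satellite for every phospho-S/T-containing fragment; −H2O/−NH3
    satellites only if requested via ``losses``; precursor ion (and its
    −H3PO4 product) when ``precursor_charge`` is given; the phospho-Tyr
    immonium marker when the peptide carries phospho-Tyr.
    """
    if max_fragment_charge < 1:
        raise ValueError("max_fragment_charge must be >= 1")
    ions = _series_ions(pep, max_fragment_charge, frozenset(losses),
                        frozenset(), precursor_charge)
    if pep.phospho_y_positions:
        ions.append(TheoreticalIon("immonium", 0, 1, LOSS_NONE,
                                   PTYR_IMMONIUM_MZ, carries_phospho=False))
    return ions


def dehydro_ion_series(
    pep: ModifiedPeptide,
    lost_sites: Iterable[int],
    max_fragment_charge: int = 1,
    losses: Iterable[str] = (),
    precursor_charge: int | None = None,
) -> list[TheoreticalIon]:
    """Ion set after phosphate loss at ``lost_sites``.

    Each lost site's residue becomes its dehydro form (Ser →
    dehydroalanine, Thr → dehydro-2-aminobutyric acid; residue − water),
    and fragments containing a lost site are flagged ``contains_dehydro``.
    With no lost sites this is identical to :func:`ion_series` minus the
    immonium marker.
    """
    sites = frozenset(lost_sites)
    st = set(pep.phospho_st_positions)
    bad = sites - st
    if bad:
        raise ValueError(
            f"lost sites {sorted(bad)} are not phospho-S/T positions"
        )
    if max_fragment_charge < 1:
        raise ValueError("max_fragment_charge must be >= 1")
    return _series_ions(pep, max_fragment_charge, frozenset(losses), sites,
                        precursor_charge)


def hypothesis_ion_set(
    pep: ModifiedPeptide,
    precursor_charge: int,
    losses: Iterable[str] = (),
    max_fragment_charge: int | None = None,
) -> list[TheoreticalIon]:
    """The full ion set a matcher should consider for one identification
    hypothesis under MSA-style fragmentation.

    Primary b/y ladders with −H3PO4 satellites, the precursor and its
    neutral-loss product, the pTyr immonium marker where relevant, plus
    the dehydro-ladder fragments (those actually containing a dehydro
    residue — the rest coincide with primary ions). Default fragment
    charge range is 1..(precursor charge − 1), floor 1, the usual
    ion-trap convention.
    """
    if max_fragment_charge is None:
        max_fragment_charge = max(1, precursor_charge - 1)
    ions = ion_series(pep, max_fragment_charge, losses,
                      precursor_charge=precursor_charge)
    st = pep.phospho_st_positions
    if st:
        for ion in dehydro_ion_series(pep, st, max_fragment_charge, losses):
            if ion.contains_dehydro:
                ions.append(ion)
    return ions


def fragment_spans(ion: TheoreticalIon, length: int, position: int) -> bool:
    """Whether a b/y fragment covers a given 1-based residue position."""
    if ion.series == "b":
        return position <= ion.index
    if ion.series == "y":
        return position > length - ion.index
    return False
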