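"""Monoisotopic mass bookkeeping for modified peptides.

Residue masses, modification deltas, peptide neutral mass, precursor and
immonium m/z, and the neutral-loss offsets that drive phosphopeptide
chemistry under CID (loss of H3PO4 from phospho-Ser/Thr).

All masses are monoisotopic and in daltons; m/z values in thomson (Th).
The residue table is carried explicitly (5 decimal places) rather than
delegated to a library so that every reported mass is auditable against
the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "CO",
    "H3PO4",
    "HPO3",
    "ModificationSpec",
    "ModifiedPeptide",
    "ProteinContext",
    "default_modifications",
    "peptide_neutral_mass",
    "precursor_mz",
    "neutral_loss_offset",
    "immonium_mz",
]

#: Monoisotopic residue masses (Da) for the 20 standard amino acids, 5 dp.
RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565  #: H2O, the peptide-bond condensation mass
PROTON = 1.00728  #: mass of a proton (charge carrier)
CO = 27.994915  #: carbonyl loss used for immonium ions
H3PO4 = 97.976896  #: phosphoric acid, the CID neutral loss from pS/pT
HPO3 = 79.966331  #: metaphosphate, the phospho modification delta

# Terminus markers usable as modification positions.
N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass modification with its residue/terminus targets."""

    name: str
    delta_mass: float
    targets: frozenset[str]
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no targets")
        import math

        if not math.isfinite(self.delta_mass):
            raise ValueError(f"modification {self.name!r} delta_mass not finite")

    def applies_to(self, residue_or_terminus: str) -> bool:
        return residue_or_terminus in self.targets


def default_modifications() -> dict[str, ModificationSpec]:
    """The default search-modification registry.

    Carbamidomethyl-Cys fixed; oxidation-Met, protein-N-terminal acetyl and
    phospho-STY variable — the standard phosphoproteomics search space.
    """
    mods = [
        ModificationSpec("Carbamidomethyl", 57.02146, frozenset("C"), fixed=True),
        ModificationSpec("Oxidation", 15.99491, frozenset("M")),
        ModificationSpec("Acetyl", 42.01057, frozenset({N_TERM})),
        ModificationSpec("Phospho", 79.96633, frozenset("STY")),
    ]
    return {m.name: m for m in mods}


PHOSPHO = default_modifications()["Phospho"]


@dataclass(frozen=True)
class ProteinContext:
    """Where a peptide sits in its parent protein."""

    preceding_residue: str | None = None
    following_residue: str | None = None
    is_protein_C_terminus: bool = False
    is_protein_N_terminus: bool = False


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence plus positioned modifications.

    Positions are 1-based residue indices, or the terminus markers
    ``"N-term"`` / ``"C-term"``. At most one modification per position;
    phospho only on S/T/Y.
    """

    sequence: str
    mods: tuple[tuple[int | str, ModificationSpec], ...] = ()
    protein_context: ProteinContext | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in RESIDUE_MASSES:
                raise ValueError(
                    f"unknown residue {ch!r} at position {i + 1} in {self.sequence!r}"
                )
        object.__setattr__(self, "mods", tuple(self.mods))
        seen: set[int | str] = set()
        n = len(self.sequence)
        for pos, spec in self.mods:
            if isinstance(pos, int):
                if not 1 <= pos <= n:
                    raise ValueError(f"mod position {pos} outside 1..{n}")
                target = self.sequence[pos - 1]
            elif pos in (N_TERM, C_TERM):
                target = pos
            else:
                raise ValueError(f"bad modification position {pos!r}")
            if pos in seen:
                raise ValueError(f"two modifications on position {pos}")
            seen.add(pos)
            if spec.name == "Phospho" and target not in "STY":
                raise ValueError(f"phospho on non-S/T/Y residue {target!r} at {pos}")
            if not spec.applies_to(target):
                raise ValueError(
                    f"modification {spec.name!r} does not target {target!r}"
                )
            if spec.name == "Acetyl" and self.protein_context is not None:
                if not self.protein_context.is_protein_N_terminus:
                    raise ValueError(
                        "protein-N-terminal acetylation on a non-N-terminal peptide"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(
            pos
            for pos, spec in self.mods
            if isinstance(pos, int) and spec.name == "Phospho"
        )

    @property
    def phospho_st_positions(self) -> tuple[int, ...]:
        """Phospho positions on Ser/Thr — the beta-elimination-capable sites."""
        return tuple(
            p for p in self.phospho_positions if self.sequence[p - 1] in "ST"
        )

    @property
    def phospho_y_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.phospho_positions if self.sequence[p - 1] == "Y")

    def mod_at(self, pos: int | str) -> ModificationSpec | None:
        for p, spec in self.mods:
            if p == pos:
                return spec
        return None

    def without_mod(self, pos: int | str) -> "ModifiedPeptide":
        return replace(
            self, mods=tuple((p, s) for p, s in self.mods if p != pos)
        )

    def label(self) -> str:
        """Human-readable form, e.g. ``VLVDQTT(ph)GLSR``."""
        tags = {"Phospho": "ph", "Oxidation": "ox", "Carbamidomethyl": "cam",
                "Acetyl": "ac"}
        out = []
        for i, ch in enumerate(self.sequence, start=1):
            out.append(ch)
            spec = self.mod_at(i)
            if spec is not None:
                out.append(f"({tags.get(spec.name, spec.name)})")
        return "".join(out)


def peptide_neutral_mass(pep: ModifiedPeptide) -> float:
    """Monoisotopic neutral mass of a modified peptide (Da).

    Sum of residue masses + one water + all modification deltas.
    """
    mass = WATER + sum(RESIDUE_MASSES[ch] for ch in pep.sequence)
    mass += sum(spec.delta_mass for _, spec in pep.mods)
    return mass


def precursor_mz(pep: ModifiedPeptide, charge: int) -> float:
    """m/z of the protonated precursor at the given charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(pep) + charge * PROTON) / charge


def neutral_loss_offset(loss_mass: float, charge: int) -> float:
    """m/z spacing between a precursor and its neutral-loss product.

    For H3PO4 this reproduces the ion-trap trigger series: 97.98 (1+),
    48.99 (2+), 32.66 (3+), 24.49 (4+).
    """
    if loss_mass <= 0:
        raise ValueError(f"loss_mass must be > 0, got {loss_mass}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return loss_mass / charge


def immonium_mz(residue: str, mods: Sequence[ModificationSpec] = ()) -> float:
    """Immonium ion m/z for a residue, optionally modified.

    Residue mass + mod deltas − CO + proton. The phospho-Tyr immonium at
    ~216.04 Th is the classic diagnostic of tyrosine phosphorylation.
    """
    if residue not in RESIDUE_MASSES:
        raise ValueError(f"unknown residue {residue!r}")
    return RESIDUE_MASSES[residue] + sum(m.delta_mass for m in mods) - CO + PROTON


#: Phospho-Tyr immonium m/z; comparisons should carry ±0.02 Th tolerance.
PTYR_IMMONIUM_MZ = immonium_mz("Y", [PHOSPHO])
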