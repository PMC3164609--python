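"""In-silico proteolytic digestion with missed-cleavage bookkeeping.

Sequential Lys-C + trypsin digestion collapses to a single trypsin rule
(cleave after K/R): Lys-C sites (after K) are a subset of trypsin sites,
so the two-enzyme protocol changes wet-lab efficiency, not the peptide
space. Proline suppression (no cleavage before P) is on by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masschem import RESIDUE_MASSES

__all__ = ["EnzymeSpec", "DigestPeptide", "TRYPSIN", "digest", "is_tryptic"]


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage rule: cut after ``cleave_after`` unless the next residue
    is in ``blocked_by_next``."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        bad = (self.cleave_after | self.blocked_by_next) - set(RESIDUE_MASSES)
        if bad:
            raise ValueError(f"invalid residue letters in enzyme spec: {sorted(bad)}")


TRYPSIN = EnzymeSpec("trypsin", frozenset("KR"), frozenset("P"))
TRYPSIN_NO_P_RULE = EnzymeSpec("trypsin/P", frozenset("KR"))


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with parent coordinates and flanking context."""

    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    preceding_residue: str | None
    following_residue: str | None
    is_protein_C_terminus: bool

    @property
    def is_protein_N_terminus(self) -> bool:
        return self.preceding_residue is None


def _cleavage_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cut."""
    n = len(sequence)
    sites = []
    for i, ch in enumerate(sequence[:-1]):
        if ch in enzyme.cleave_after and sequence[i + 1] not in enzyme.blocked_by_next:
            sites.append(i)
    return sites


def digest(
    protein_sequence: str, enzyme: EnzymeSpec = TRYPSIN, max_missed: int = 2
) -> list[DigestPeptide]:
    """Enumerate every peptide bounded by cleavage sites (or termini) with
    0..max_missed internal missed sites.

    Peptides are returned in order of start position, then length.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    for i, ch in enumerate(protein_sequence):
        if ch not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")

    n = len(protein_sequence)
    sites = _cleavage_sites(protein_sequence, enzyme)
    # Fragment boundaries: starts of 0-missed peptides (0-based).
    starts = [0] + [s + 1 for s in sites]
    ends = [s for s in sites] + [n - 1]  # inclusive 0-based ends

    out: list[DigestPeptide] = []
    k = len(starts)
    for i in range(k):
        for j in range(i, min(i + max_missed + 1, k)):
            s0, e0 = starts[i], ends[j]
            out.append(
                DigestPeptide(
                    sequence=protein_sequence[s0 : e0 + 1],
                    start=s0 + 1,
                    end=e0 + 1,
                    missed_cleavages=j - i,
                    preceding_residue=protein_sequence[s0 - 1] if s0 > 0 else None,
                    following_residue=(
                        protein_sequence[e0 + 1] if e0 + 1 < n else None
                    ),
                    is_protein_C_terminus=(e0 == n - 1),
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def is_tryptic(
    pep: DigestPeptide, enzyme: EnzymeSpec = TRYPSIN
) -> tuple[bool, str]:
    """Full tryptic specificity check; returns (flag, reason).

    Both termini must be cleavage-consistent: the N-terminus preceded by a
    cleavage residue or the protein start, the C-terminus ending in a
    cleavage residue or being the protein C-terminus.
    """
    if pep.preceding_residue is None:
        n_ok, n_reason = True, "protein N-terminus"
    elif pep.preceding_residue in enzyme.cleave_after and (
        pep.sequence[0] not in enzyme.blocked_by_next
    ):
        n_ok, n_reason = True, f"preceded by {pep.preceding_residue}"
    else:
        n_ok, n_reason = False, f"preceded by {pep.preceding_residue} (non-tryptic)"

    if pep.is_protein_C_terminus:
        c_ok, c_reason = True, "protein C-terminus"
    elif pep.sequence[-1] in enzyme.cleave_after and (
        pep.following_residue is None
        or pep.following_residue not in enzyme.blocked_by_next
    ):
        c_ok, c_reason = True, f"ends in {pep.sequence[-1]}"
    else:
        c_ok, c_reason = False, f"ends in {pep.sequence[-1]} (non-tryptic)"

    return n_ok and c_ok, f"N: {n_reason}; C: {c_reason}"
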