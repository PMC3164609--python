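"""Peak-to-ion assignment, run statistics and the identification score.

Matching is greedy nearest-Δ within a fragment tolerance, fully
deterministic: candidate (ion, peak) pairs are taken in order of |Δm/z|,
each peak and each theoretical ion used at most once; on an exact |Δ| tie
the primary (no-loss) ion wins.

The identification score is intentionally simple plumbing — a −10·log10
binomial-tail probability of seeing at least the observed number of ion
matches by chance, with the per-ion chance-match probability estimated
from the peak density inside the tolerance window. It stands where a
search-engine score would in a real workflow and is calibrated only in
the sense that random spectra score near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fragments import LOSS_NONE, TheoreticalIon
from .masschem import PROTON

__all__ = ["Spectrum", "PeakAssignment", "MatchReport", "match",
           "longest_run", "plumbing_score"]


@dataclass(frozen=True)
class Spectrum:
    """A peak list with its precursor, MGF-backed."""

    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), m/z-sorted
    title: str = ""
    provenance: str = "unknown"  # MSA | MS2 | MS3 | unknown

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass(frozen=True)
class PeakAssignment:
    peak_index: int
    peak_mz: float
    peak_intensity: float
    ion: TheoreticalIon
    delta_mz: float  # observed − theoretical


@dataclass(frozen=True)
class MatchReport:
    """Annotated assignment of a spectrum to one peptide hypothesis."""

    assignments: tuple[PeakAssignment, ...]
    matched_b_positions: frozenset[int]
    matched_y_positions: frozenset[int]
    longest_b_run: int
    longest_y_run: int
    abundant_b_positions: frozenset[int]
    abundant_y_positions: frozenset[int]
    precursor_error_ppm: float | None
    plumbing_score: float
    frag_tol: float
    abundance_floor: float
    ions_total: int
    peaks_total: int

    def matched_ions(self) -> list[TheoreticalIon]:
        return [a.ion for a in self.assignments]


def longest_run(positions: set[int] | frozenset[int]) -> int:
    """Length of the longest run of consecutive integers in the set."""
    if not positions:
        return 0
    best = run = 1
    prev = None
    for p in sorted(positions):
        if prev is not None and p == prev + 1:
            run += 1
            best = max(best, run)
        else:
            run = 1
        prev = p
    return max(best, run)


def plumbing_score(
    n_matched: int, ions_total: int, peaks_total: int,
    frag_tol: float, mz_span: float,
) -> float:
    """−10·log10 binomial tail P(X ≥ n_matched) with X ~ Bin(ions_total, p),
    p = chance of a random peak landing inside one tolerance window."""
    if n_matched <= 0 or peaks_total <= 0 or ions_total <= 0:
        return 0.0
    span = max(mz_span, 2 * frag_tol)
    p_window = min(1.0, 2 * frag_tol / span)
    # P(at least one of peaks_total peaks in the window)
    p_ion = 1.0 - (1.0 - p_window) ** peaks_total
    logsf = stats.binom.logsf(n_matched - 1, ions_total, p_ion)
    return max(0.0, -10.0 / math.log(10.0) * logsf)


def match(
    spec: Spectrum,
    ions: list[TheoreticalIon],
    frag_tol: float = 0.5,
    prec_tol_ppm: float = 10.0,
    abundance_floor: float = 0.05,
) -> MatchReport:
    """Assign observed peaks to theoretical ions within ``frag_tol`` (Da).

    A backbone position counts as matched if its primary ion OR any of
    its loss satellites matched; "abundant" restricts that to peaks with
    intensity ≥ ``abundance_floor`` × base peak. The precursor error (ppm)
    is measured against the theoretical precursor ion when one is in the
    ion list.
    """
    if frag_tol <= 0 or prec_tol_ppm <= 0:
        raise ValueError("tolerances must be positive")
    if not 0 <= abundance_floor < 1:
        raise ValueError("abundance_floor must be in [0, 1)")

    mz = spec.mz_array
    inten = spec.intensity_array
    n_peaks = len(mz)

    # Candidate pairs, deterministic greedy by |Δ| then primary-first.
    candidates: list[tuple[float, int, int, int]] = []
    for ii, ion in enumerate(ions):
        if n_peaks == 0:
            break
        j = int(np.searchsorted(mz, ion.mz))
        for k in (j - 1, j):
            if 0 <= k < n_peaks:
                d = abs(mz[k] - ion.mz)
                if d <= frag_tol:
                    pref = 0 if ion.loss_state == LOSS_NONE else 1
                    candidates.append((d, pref, ii, k))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    assignments: list[PeakAssignment] = []
    for d, _, ii, k in candidates:
        if ii in used_ions or k in used_peaks:
            continue
        used_ions.add(ii)
        used_peaks.add(k)
        ion = ions[ii]
        assignments.append(
            PeakAssignment(k, float(mz[k]), float(inten[k]), ion,
                           float(mz[k] - ion.mz))
        )
    assignments.sort(key=lambda a: a.peak_mz)

    base = spec.base_peak_intensity
    floor = abundance_floor * base
    b_pos, y_pos, ab_b, ab_y = set(), set(), set(), set()
    for a in assignments:
        if a.ion.series == "b":
            b_pos.add(a.ion.index)
            if a.peak_intensity >= floor:
                ab_b.add(a.ion.index)
        elif a.ion.series == "y":
            y_pos.add(a.ion.index)
            if a.peak_intensity >= floor:
                ab_y.add(a.ion.index)

    prec_theo = next(
        (i for i in ions
         if i.series == "precursor" and i.loss_state == LOSS_NONE
         and i.charge == spec.precursor_charge),
        None,
    )
    prec_err = (
        (spec.precursor_mz - prec_theo.mz) / prec_theo.mz * 1e6
        if prec_theo is not None else None
    )

    span = float(mz[-1] - mz[0]) if n_peaks >= 2 else 0.0
    score = plumbing_score(len(assignments), len(ions), n_peaks, frag_tol, span)

    return MatchReport(
        assignments=tuple(assignments),
        matched_b_positions=frozenset(b_pos),
        matched_y_positions=frozenset(y_pos),
        longest_b_run=longest_run(b_pos),
        longest_y_run=longest_run(y_pos),
        abundant_b_positions=frozenset(ab_b),
        abundant_y_positions=frozenset(ab_y),
        precursor_error_ppm=prec_err,
        plumbing_score=score,
        frag_tol=frag_tol,
        abundance_floor=abundance_floor,
        ions_total=len(ions),
        peaks_total=n_peaks,
    )
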