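"""Phospho-site localization by isoform enumeration and diagnostic ions.

Every placement of the claimed number of phosphates over the peptide's
S/T/Y sites is enumerated; each isoform's theoretical ion set is matched
against the spectrum, and the isoform is scored by the number of matched
*site-determining* ions — fragments whose m/z (or existence) differs from
at least one competing isoform. This is the automated form of the manual
"which y/b ions pin the site" reasoning: for VLVDQTT(ph)GLSR, y5 and b7
are exactly such ions.

The score is a plain count, not a probability; the plumbing score only
breaks count ties, and a zero margin between the best and runner-up
isoform is reported as ambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .config import PipelineConfig
from .fragments import TheoreticalIon, hypothesis_ion_set
from .masschem import ModificationSpec, ModifiedPeptide, PHOSPHO
from .matching import Spectrum, match

__all__ = ["SiteAssignment", "enumerate_isoforms", "localize"]


@dataclass(frozen=True)
class SiteAssignment:
    best_isoform: ModifiedPeptide
    assigned_positions: tuple[int, ...]
    candidate_scores: dict
    diagnostic_ions: tuple[TheoreticalIon, ...]
    ambiguous: bool
    margin: int
    runner_up: ModifiedPeptide | None
    tied_isoforms: tuple[ModifiedPeptide, ...]

    def site_labels(self) -> tuple[str, ...]:
        seq = self.best_isoform.sequence
        return tuple(f"{seq[p - 1]}{p}" for p in self.assigned_positions)


def enumerate_isoforms(
    sequence: str,
    n_phospho: int,
    other_mods: tuple[tuple[int | str, ModificationSpec], ...] = (),
) -> list[ModifiedPeptide]:
    """All placements of ``n_phospho`` phosphates over S/T/Y sites,
    other modifications held fixed. Count = C(#sites, n_phospho)."""
    if n_phospho < 0:
        raise ValueError("n_phospho must be >= 0")
    sites = [i for i, ch in enumerate(sequence, start=1) if ch in "STY"]
    if n_phospho > len(sites):
        raise ValueError(
            f"{n_phospho} phosphates requested but only {len(sites)} "
            f"S/T/Y site(s) in {sequence!r}"
        )
    out = []
    for combo in itertools.combinations(sites, n_phospho):
        mods = tuple(other_mods) + tuple((p, PHOSPHO) for p in combo)
        out.append(ModifiedPeptide(sequence, mods))
    return out


def _site_determining(
    ion_sets: list[list[TheoreticalIon]], eps: float
) -> list[set]:
    """For each isoform, the keys of its ions that differ (in m/z or
    existence) from at least one other isoform."""
    maps = [{ion.key(): ion.mz for ion in ions} for ions in ion_sets]
    sd: list[set] = []
    for i, mi in enumerate(maps):
        keys = set()
        for key, mz in mi.items():
            for j, mj in enumerate(maps):
                if i == j:
                    continue
                other = mj.get(key)
                if other is None or abs(other - mz) > eps:
                    keys.add(key)
                    break
        sd.append(keys)
    return sd


def localize(
    spec: Spectrum,
    sequence: str,
    n_phospho: int,
    other_mods: tuple[tuple[int | str, ModificationSpec], ...] = (),
    config: PipelineConfig | None = None,
) -> SiteAssignment:
    """Assign phospho sites for one spectrum by diagnostic-ion counting.

    Ties on the diagnostic count fall back to the plumbing score to pick
    the reported best; if the count margin is zero the assignment is
    flagged ambiguous and all tied isoforms listed.
    """
    if config is None:
        config = PipelineConfig()
    if not spec.peaks:
        raise ValueError("empty spectrum")
    isoforms = enumerate_isoforms(sequence, n_phospho, other_mods)

    ion_sets = [
        hypothesis_ion_set(iso, spec.precursor_charge, losses=config.losses)
        for iso in isoforms
    ]
    sd_keys = _site_determining(ion_sets, eps=config.frag_tol_da)

    scored = []
    for iso, ions, sd in zip(isoforms, ion_sets, sd_keys):
        report = match(spec, ions, frag_tol=config.frag_tol_da,
                       prec_tol_ppm=config.prec_tol_ppm,
                       abundance_floor=config.abundance_floor)
        matched_sd = tuple(
            a.ion for a in report.assignments if a.ion.key() in sd
        )
        scored.append((iso, len(matched_sd), report.plumbing_score, matched_sd))

    # Deterministic best: count desc, plumbing desc, positions asc.
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i][1], -scored[i][2],
                       scored[i][0].phospho_positions),
    )
    best_i = order[0]
    best_iso, best_count, _, best_sd = scored[best_i]

    others = order[1:]
    margin = 0
    runner = None
    tied: list[ModifiedPeptide] = []
    if others:
        runner_count = max(scored[i][1] for i in others)
        margin = best_count - runner_count
        tied = [best_iso] + [
            scored[i][0] for i in others if scored[i][1] == best_count
        ] if margin == 0 else []
        # runner-up: highest count; break ties by site-index distance
        def dist(i: int) -> int:
            a, b = best_iso.phospho_positions, scored[i][0].phospho_positions
            return sum(abs(x - y) for x, y in zip(a, b)) if a and b else 0
        runners = [i for i in others if scored[i][1] == runner_count]
        runner = scored[min(runners, key=dist)][0]

    return SiteAssignment(
        best_isoform=best_iso,
        assigned_positions=best_iso.phospho_positions,
        candidate_scores={
            iso.label(): {"diagnostic_ions_matched": c, "plumbing_score": s}
            for iso, c, s, _ in scored
        },
        diagnostic_ions=best_sd,
        ambiguous=bool(others) and margin == 0,
        margin=margin,
        runner_up=runner,
        tied_isoforms=tuple(tied),
    )
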