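"""The acceptance rule engine for phosphopeptide identifications.

Rules, applied in order and recorded in an auditable trace:

R1  identification score above threshold (default > 20);
R2  at least ``run_length_min`` (default 4) consecutive y-ions AND b-ions
    assigned to abundant signals (mode "either" relaxes to one series);
R3  special case — a peptide lacking a C-terminal K/R because it sits at
    the protein C-terminus is accepted on a b-run alone;
R4  special case — a peptide with C-terminal Lys and N-terminal Arg from
    a missed cleavage is accepted on a b-run alone;
R5  claimed phospho-Ser/Thr requires phosphate evidence: a precursor
    −H3PO4/z neutral-loss peak, matched dehydro-residue fragments
    (dehydroalanine / dehydro-2-aminobutyric acid ladders), or matched
    intact-phospho fragments;
R6  claimed phospho-Tyr requires the ~216.04 Th phosphotyrosine immonium
    ion or matched intact-pTyr fragments;
R7  proline-containing peptides get a warning (intense proline-directed
    signals can suppress the rest of the spectrum) — never a rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .fragments import LOSS_H3PO4, LOSS_NONE, fragment_spans, hypothesis_ion_set
from .matching import MatchReport, Spectrum, longest_run, match
from .masschem import ModifiedPeptide

__all__ = ["ValidationVerdict", "validate", "validate_batch", "BatchSummary"]

SPECIAL_NONE = "none"
SPECIAL_C_TERM = "protein_C_terminus"
SPECIAL_MISSED_RK = "missed_cleavage_RK"


@dataclass(frozen=True)
class ValidationVerdict:
    accepted: bool
    rule_trace: tuple[tuple[str, str, str], ...]  # (rule_id, outcome, evidence)
    score_used: float
    applied_special_case: str
    phospho_evidence: frozenset[str]
    warnings: tuple[str, ...]

    def trace_text(self) -> str:
        return "; ".join(f"{r}:{o}({e})" for r, o, e in self.rule_trace)


def _phospho_evidence(pep: ModifiedPeptide, report: MatchReport,
                      frag_tol: float) -> tuple[frozenset[str], list[str]]:
    """Scan matched ions for the four phosphate fingerprints."""
    evidence: set[str] = set()
    notes: list[str] = []
    n = len(pep.sequence)
    st = set(pep.phospho_st_positions)
    py = set(pep.phospho_y_positions)
    for a in report.assignments:
        ion = a.ion
        if ion.series == "precursor" and ion.loss_state == LOSS_H3PO4:
            evidence.add("precursor_NL")
            notes.append(f"precursor NL at {a.peak_mz:.4f}")
        elif ion.contains_dehydro or (
            ion.series in "by" and ion.loss_state == LOSS_H3PO4
        ):
            evidence.add("dehydro_fragments")
        elif (ion.series in "by" and ion.loss_state == LOSS_NONE
              and ion.carries_phospho):
            evidence.add("intact_phospho_fragments")
        elif ion.series == "immonium":
            evidence.add("pTyr_immonium")
            notes.append(f"pTyr immonium at {a.peak_mz:.4f}")
        if py and ion.series in "by" and ion.loss_state == LOSS_NONE:
            if any(fragment_spans(ion, n, p) for p in py):
                evidence.add("intact_phospho_fragments")
    # evidence kinds only meaningful for the claimed site classes
    if not st:
        evidence -= {"precursor_NL", "dehydro_fragments"}
        if not py:
            evidence.discard("intact_phospho_fragments")
    return frozenset(evidence), notes


def validate(
    pep: ModifiedPeptide, report: MatchReport, config: PipelineConfig,
    external_score: float | None = None,
) -> ValidationVerdict:
    """Apply the acceptance rules to one matched identification.

    ``external_score`` substitutes a search-engine score for the built-in
    plumbing score against the same threshold.
    """
    trace: list[tuple[str, str, str]] = []
    warnings: list[str] = []

    score = report.plumbing_score if external_score is None else external_score
    r1 = score > config.score_threshold
    trace.append(("R1", "pass" if r1 else "fail",
                  f"score {score:.1f} vs threshold {config.score_threshold:g}"))

    k = config.run_length_min
    b_run = longest_run(report.abundant_b_positions)
    y_run = longest_run(report.abundant_y_positions)
    if config.consecutive_rule_mode == "both":
        r2 = b_run >= k and y_run >= k
    else:
        r2 = b_run >= k or y_run >= k
    trace.append(("R2", "pass" if r2 else "fail",
                  f"abundant runs b={b_run} y={y_run}, need {k} "
                  f"({config.consecutive_rule_mode})"))

    special = SPECIAL_NONE
    series_ok = r2
    ctx = pep.protein_context
    if not r2:
        if (ctx is not None and ctx.is_protein_C_terminus
                and pep.sequence[-1] not in "KR" and b_run >= k):
            special, series_ok = SPECIAL_C_TERM, True
            trace.append(("R3", "pass",
                          f"protein C-terminal peptide, b-run {b_run} >= {k}"))
        else:
            trace.append(("R3", "not_applied", "no C-terminal special case"))
        if special == SPECIAL_NONE:
            if (pep.sequence[-1] == "K" and pep.sequence[0] == "R"
                    and b_run >= k):
                special, series_ok = SPECIAL_MISSED_RK, True
                trace.append(("R4", "pass",
                              f"R...K missed-cleavage peptide, b-run {b_run} >= {k}"))
            else:
                trace.append(("R4", "not_applied", "no R...K special case"))

    evidence, notes = _phospho_evidence(pep, report, config.frag_tol_da)
    st_claimed = bool(pep.phospho_st_positions)
    y_claimed = bool(pep.phospho_y_positions)
    st_kinds = {"precursor_NL", "dehydro_fragments", "intact_phospho_fragments"}
    y_kinds = {"pTyr_immonium", "intact_phospho_fragments"}
    r5 = (not st_claimed) or bool(evidence & st_kinds)
    r6 = (not y_claimed) or bool(evidence & y_kinds)
    trace.append(("R5", "pass" if r5 else "fail" if st_claimed else "not_applied",
                  f"pS/pT evidence: {sorted(evidence & st_kinds)} {notes}"))
    trace.append(("R6", "pass" if r6 else "fail" if y_claimed else "not_applied",
                  f"pY evidence: {sorted(evidence & y_kinds)}"))

    if "P" in pep.sequence:
        warnings.append("proline present: intense proline-directed signals "
                        "may suppress other fragments")
        trace.append(("R7", "warn", "proline residue(s) in sequence"))
    else:
        trace.append(("R7", "not_applied", "no proline"))

    accepted = r1 and series_ok and r5 and r6
    return ValidationVerdict(
        accepted=accepted,
        rule_trace=tuple(trace),
        score_used=score,
        applied_special_case=special,
        phospho_evidence=evidence,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class BatchSummary:
    table: pd.DataFrame
    n_accepted: int
    n_phosphopeptides: int  # distinct accepted phosphopeptide sequences
    n_proteins: int  # distinct parent proteins of accepted phosphopeptides
    accepted_phosphopeptides: tuple[str, ...]
    accepted_proteins: tuple[str, ...]


def validate_batch(
    items: list[tuple[ModifiedPeptide, Spectrum]],
    config: PipelineConfig,
    proteins: list[str] | None = None,
) -> BatchSummary:
    """Match and validate a batch of (peptide hypothesis, spectrum) pairs.

    ``proteins`` optionally maps each item to its parent protein
    identifier for the distinct-protein count.
    """
    if not items:
        raise ValueError("empty batch")
    if proteins is not None and len(proteins) != len(items):
        raise ValueError("proteins must align with items")

    rows = []
    accepted_seqs: set[str] = set()
    accepted_prots: set[str] = set()
    for idx, (pep, spec) in enumerate(items):
        ions = hypothesis_ion_set(pep, spec.precursor_charge,
                                  losses=config.losses)
        report = match(spec, ions, frag_tol=config.frag_tol_da,
                       prec_tol_ppm=config.prec_tol_ppm,
                       abundance_floor=config.abundance_floor)
        verdict = validate(pep, report, config)
        is_phospho = bool(pep.phospho_positions)
        prot = proteins[idx] if proteins is not None else ""
        if verdict.accepted and is_phospho:
            accepted_seqs.add(pep.label())
            if prot:
                accepted_prots.add(prot)
        rows.append({
            "title": spec.title,
            "peptide": pep.label(),
            "sequence": pep.sequence,
            "protein": prot,
            "charge": spec.precursor_charge,
            "is_phospho": is_phospho,
            "score": verdict.score_used,
            "precursor_error_ppm": report.precursor_error_ppm,
            "accepted": verdict.accepted,
            "special_case": verdict.applied_special_case,
            "phospho_evidence": ",".join(sorted(verdict.phospho_evidence)),
            "rule_trace": verdict.trace_text(),
        })
    table = pd.DataFrame(rows)
    return BatchSummary(
        table=table,
        n_accepted=int(table["accepted"].sum()),
        n_phosphopeptides=len(accepted_seqs),
        n_proteins=len(accepted_prots),
        accepted_phosphopeptides=tuple(sorted(accepted_seqs)),
        accepted_proteins=tuple(sorted(accepted_prots)),
    )
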