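"""The acceptance rule engine: score, consecutive-ion rule, C-terminal
special cases, phosphate-evidence requirements."""

import dataclasses

import numpy as np
import pytest

from phosphoval import (
    PHOSPHO,
    ModifiedPeptide,
    PipelineConfig,
    ProteinContext,
    Spectrum,
    SimulationConfig,
    ion_series,
    match,
    precursor_mz,
    simulate,
    validate,
    validate_batch,
)
from phosphoval.fragments import hypothesis_ion_set
from phosphoval.synthetic import TABLE_PEPTIDES, make_fixture


def _report_for(pep, spec, config):
    ions = hypothesis_ion_set(pep, spec.precursor_charge,
                              losses=config.losses)
    return match(spec, ions, frag_tol=config.frag_tol_da,
                 abundance_floor=config.abundance_floor)


def _partial_spectrum(pep, b_idx, y_idx, charge=2, extra=()):
    ions = [i for i in ion_series(pep, 1)
            if i.loss_state == "none" and (
                (i.series == "b" and i.index in b_idx)
                or (i.series == "y" and i.index in y_idx))]
    peaks = tuple((i.mz, 100.0) for i in ions) + tuple(extra)
    return Spectrum(precursor_mz=precursor_mz(pep, charge),
                    precursor_charge=charge, peaks=peaks)


class TestValidate:
    def test_full_coverage_phosphopeptide_accepted(self, fig_phosphopeptide,
                                                   config):
        spec = simulate(fig_phosphopeptide, 2,
                        SimulationConfig(seed=5))[0]
        report = _report_for(fig_phosphopeptide, spec, config)
        verdict = validate(fig_phosphopeptide, report, config)
        assert verdict.accepted
        assert "precursor_NL" in verdict.phospho_evidence
        assert "intact_phospho_fragments" in verdict.phospho_evidence

    def test_short_runs_rejected_at_r2(self, config):
        pep = ModifiedPeptide("GAVLIMEFK")
        spec = _partial_spectrum(pep, {1, 2, 3}, {1, 2, 3})
        verdict = validate(pep, _report_for(pep, spec, config), config)
        assert not verdict.accepted
        r2 = dict((r, o) for r, o, _ in verdict.rule_trace)["R2"]
        assert r2 == "fail"

    def test_protein_c_terminal_special_case(self, config):
        pep = ModifiedPeptide(
            "GAVLIMEFG",
            protein_context=ProteinContext(preceding_residue="K",
                                           is_protein_C_terminus=True))
        spec = _partial_spectrum(pep, {1, 2, 3, 4, 5}, set())
        verdict = validate(pep, _report_for(pep, spec, config), config)
        assert verdict.accepted
        assert verdict.applied_special_case == "protein_C_terminus"

    def test_missed_cleavage_rk_special_case(self, config):
        pep = ModifiedPeptide("RGAVLIMEK")
        spec = _partial_spectrum(pep, {2, 3, 4, 5}, set())
        verdict = validate(pep, _report_for(pep, spec, config), config)
        assert verdict.accepted
        assert verdict.applied_special_case == "missed_cleavage_RK"

    def test_claimed_phospho_without_evidence_rejected(self, config):
        # phospho claimed but the spectrum shows only phospho-free fragments
        pep = ModifiedPeptide("GAVLIMESK", ((8, PHOSPHO),))
        spec = _partial_spectrum(pep, {1, 2, 3, 4, 5, 6}, set())
        verdict = validate(pep, _report_for(pep, spec, config), config)
        assert not verdict.accepted
        r5 = dict((r, o) for r, o, _ in verdict.rule_trace)["R5"]
        assert r5 == "fail"

    def test_proline_is_warning_not_rejection(self, config):
        pep = ModifiedPeptide("GPAVLIMESK", ((9, PHOSPHO),))
        spec = simulate(pep, 2, SimulationConfig(seed=9))[0]
        verdict = validate(pep, _report_for(pep, spec, config), config)
        assert verdict.accepted
        assert verdict.warnings

    def test_either_mode_relaxes_r2(self, config):
        pep = ModifiedPeptide("GAVLIMEFK")
        spec = _partial_spectrum(pep, {1, 2, 3, 4, 5}, set())
        strict = validate(pep, _report_for(pep, spec, config), config)
        relaxed_cfg = dataclasses.replace(config,
                                          consecutive_rule_mode="either")
        relaxed = validate(pep, _report_for(pep, spec, relaxed_cfg),
                           relaxed_cfg)
        assert not strict.accepted
        assert relaxed.accepted

    def test_adding_evidence_never_flips_to_rejected(self, config):
        # monotonicity: extending the matched ladder cannot hurt
        pep = ModifiedPeptide("GAVLIMEFK")
        n = len(pep.sequence)
        prev_accepted = False
        for k in range(2, n):
            idx = set(range(1, k + 1))
            spec = _partial_spectrum(pep, idx, idx)
            verdict = validate(pep, _report_for(pep, spec, config), config)
            assert not (prev_accepted and not verdict.accepted)
            prev_accepted = verdict.accepted
        assert prev_accepted

    def test_external_score_substitution(self, fig_phosphopeptide, config):
        spec = simulate(fig_phosphopeptide, 2, SimulationConfig(seed=5))[0]
        report = _report_for(fig_phosphopeptide, spec, config)
        low = validate(fig_phosphopeptide, report, config, external_score=5.0)
        assert not low.accepted
        assert low.score_used == 5.0


class TestValidateBatch:
    def test_table_roster_with_decoys(self, config):
        fixture = make_fixture("SIMAC_MSA", seed=3)
        summary = validate_batch(list(fixture.items), config,
                                 list(fixture.proteins))
        assert summary.n_phosphopeptides == 6
        assert summary.n_proteins == 3

    def test_pure_noise_yields_no_acceptances(self, config):
        rng = np.random.default_rng(11)
        items = []
        for entry in TABLE_PEPTIDES[:3]:
            pep = entry.peptide()
            peaks = tuple(
                (float(m), 100.0)
                for m in sorted(rng.uniform(100, 1200, size=30)))
            items.append((pep, Spectrum(
                precursor_mz=precursor_mz(pep, 2), precursor_charge=2,
                peaks=peaks)))
        summary = validate_batch(items, config)
        assert summary.n_accepted == 0

    def test_duplicate_spectra_deduplicated(self, fig_phosphopeptide, config):
        spec = simulate(fig_phosphopeptide, 2, SimulationConfig(seed=5))[0]
        items = [(fig_phosphopeptide, spec), (fig_phosphopeptide, spec)]
        summary = validate_batch(items, config, ["HuR", "HuR"])
        assert summary.n_accepted == 2
        assert summary.n_phosphopeptides == 1
        assert summary.n_proteins == 1

    def test_empty_batch_rejected(self, config):
        with pytest.raises(ValueError):
            validate_batch([], config)
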