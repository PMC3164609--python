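"""Site localization: isoform enumeration, diagnostic-ion scoring,
brute-force oracle agreement."""

import itertools
import math

import numpy as np
import pytest
from pyteomics import mass as ptmass

from phosphoval import (
    PHOSPHO,
    ModifiedPeptide,
    PipelineConfig,
    SimulationConfig,
    Spectrum,
    enumerate_isoforms,
    ion_series,
    localize,
    precursor_mz,
    simulate,
)
from phosphoval.localization import _site_determining
from phosphoval.fragments import hypothesis_ion_set

from conftest import noiseless_spectrum


class TestEnumerateIsoforms:
    def test_fig2_three_single_phospho_isoforms(self):
        isos = enumerate_isoforms("VLVDQTTGLSR", 1)
        assert {i.phospho_positions for i in isos} == {(6,), (7,), (10,)}

    def test_zero_phospho_identity(self):
        isos = enumerate_isoforms("VLVDQTTGLSR", 0)
        assert len(isos) == 1 and not isos[0].mods

    def test_two_serine_peptide(self):
        isos = enumerate_isoforms("DLSSIFR", 1)
        assert {i.phospho_positions for i in isos} == {(3,), (4,)}

    def test_combinatorial_count(self):
        seq = "SATSYLK"  # sites S1, T3, S4, Y5
        for n in range(0, 5):
            assert len(enumerate_isoforms(seq, n)) == math.comb(4, n)

    def test_too_many_phosphates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_isoforms("GAVLK", 1)


class TestSiteDetermining:
    def test_symmetric_between_isoform_pairs(self):
        isos = enumerate_isoforms("VLVDQTTGLSR", 1)
        sets = [ion_series(i, 1) for i in isos]
        for a, b in itertools.combinations(range(len(isos)), 2):
            sd = _site_determining([sets[a], sets[b]], eps=0.5)
            # compare as positions: satellites exist only where the
            # fragment carries phospho, so loss states are asymmetric
            pos_a = {k[:2] for k in sd[0]}
            pos_b = {k[:2] for k in sd[1]}
            assert pos_a == pos_b


class TestLocalize:
    def test_fig2_site_and_diagnostics(self, fig_phosphopeptide, config):
        spec = noiseless_spectrum(fig_phosphopeptide)
        sa = localize(spec, "VLVDQTTGLSR", 1, (), config)
        assert sa.assigned_positions == (7,)
        assert not sa.ambiguous
        assert sa.site_labels() == ("T7",)
        diag = {(i.series, i.index) for i in sa.diagnostic_ions}
        assert ("y", 5) in diag
        assert ("b", 7) in diag

    def test_shared_ions_only_is_ambiguous(self, config):
        # b1-b5 and y1-y4 do not separate T6 from T7
        pep = ModifiedPeptide("VLVDQTTGLSR", ((7, PHOSPHO),))
        ions = [i for i in ion_series(pep, 1)
                if i.loss_state == "none" and (
                    (i.series == "b" and i.index <= 5)
                    or (i.series == "y" and i.index <= 4))]
        spec = Spectrum(precursor_mz=precursor_mz(pep, 2),
                        precursor_charge=2,
                        peaks=tuple((i.mz, 100.0) for i in ions))
        sa = localize(spec, "VLVDQTTGLSR", 1, (), config)
        assert sa.ambiguous
        assert sa.margin == 0
        assert len(sa.tied_isoforms) >= 2

    def test_empty_spectrum_rejected(self, config):
        spec = Spectrum(precursor_mz=500.0, precursor_charge=2, peaks=())
        with pytest.raises(ValueError):
            localize(spec, "VLVDQTTGLSR", 1, (), config)

    def test_no_sites_with_phospho_claimed_rejected(self, config):
        spec = Spectrum(precursor_mz=500.0, precursor_charge=2,
                        peaks=((200.0, 1.0),))
        with pytest.raises(ValueError):
            localize(spec, "GAVLK", 1, (), config)

    @pytest.mark.parametrize("seq,planted", [
        ("VLVDQTTGLSR", 6), ("VLVDQTTGLSR", 10), ("DLSSIFR", 4),
        ("SLFSSIGEVESAK", 4), ("TAVINAASGR", 8),
    ])
    def test_noiseless_full_coverage_unambiguous(self, seq, planted, config):
        pep = ModifiedPeptide(seq, ((planted, PHOSPHO),))
        sa = localize(noiseless_spectrum(pep), seq, 1, (), config)
        assert not sa.ambiguous
        assert sa.assigned_positions == (planted,)

    def test_agrees_with_brute_force_oracle_on_clean_spectra(self, config):
        """Independent oracle: score each isoform by counting observed
        peaks that sit (within tolerance) on ions unique to it, ion m/z
        computed element-wise with pyteomics."""
        rng = np.random.default_rng(42)
        AA = list("ACDEFGHIKLMNPQRSTVWY")
        tol = config.frag_tol_da
        for _ in range(50):
            while True:
                L = int(rng.integers(8, 13))
                seq = "".join(rng.choice(AA, size=L - 1)) + \
                    str(rng.choice(["K", "R"]))
                sites = [i for i, ch in enumerate(seq, 1) if ch in "ST"]
                if len(sites) >= 2:
                    break
            planted = int(rng.choice(sites))
            pep = ModifiedPeptide(seq, ((planted, PHOSPHO),))
            spec = noiseless_spectrum(pep)
            mzs = [m for m, _ in spec.peaks]

            # oracle: singly charged b/y m/z per isoform via pyteomics
            iso_tables = {}
            for s in sites + [i for i, c in enumerate(seq, 1) if c == "Y"]:
                table = {}
                for i in range(1, L):
                    b = ptmass.fast_mass(seq[:i], ion_type="b", charge=1)
                    y = ptmass.fast_mass(seq[i:], ion_type="y", charge=1)
                    if s <= i:
                        b += 79.96633
                    if s > i:
                        y += 79.96633
                    table[("b", i)] = b
                    table[("y", L - i)] = y
                iso_tables[s] = table
            def oracle_score(s):
                count = 0
                for key, mz in iso_tables[s].items():
                    others = [iso_tables[t][key] for t in iso_tables if t != s]
                    if all(abs(mz - o) <= tol for o in others):
                        continue  # shared ion, not site-determining
                    if any(abs(mz - p) <= tol for p in mzs):
                        count += 1
                return count
            scores = {s: oracle_score(s) for s in iso_tables}
            best = max(scores, key=scores.get)
            top = [s for s, c in scores.items() if c == scores[best]]

            sa = localize(spec, seq, 1, (), config)
            assert len(top) == 1
            assert sa.assigned_positions == (best,) == (planted,)

    def test_planted_site_recovery_under_dropout_and_noise(self, config):
        """>= 95% recovery at dropout 0.3 with 20 noise peaks, 200 trials."""
        rng = np.random.default_rng(123)
        AA = list("ACDEFGHIKLMNPQRSTVWY")
        recovered = 0
        trials = 200
        for _ in range(trials):
            while True:
                L = int(rng.integers(8, 13))
                seq = "".join(rng.choice(AA, size=L - 1)) + \
                    str(rng.choice(["K", "R"]))
                sites = [i for i, ch in enumerate(seq, 1) if ch in "ST"]
                if len(sites) >= 2:
                    break
            planted = int(rng.choice(sites))
            pep = ModifiedPeptide(seq, ((planted, PHOSPHO),))
            sim = SimulationConfig(seed=int(rng.integers(0, 2**31 - 1)),
                                   dropout_prob=0.3, noise_peaks=20)
            spec = simulate(pep, 2, sim)[0]
            sa = localize(spec, seq, 1, (), config)
            if not sa.ambiguous and sa.assigned_positions == (planted,):
                recovered += 1
        assert recovered / trials >= 0.95
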