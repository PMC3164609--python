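import pytest

from phosphoval import (
    PHOSPHO,
    ModifiedPeptide,
    PipelineConfig,
    Spectrum,
    ion_series,
    precursor_mz,
)

FIG_PEPTIDE = "VLVDQTTGLSR"


@pytest.fixture
def fig_phosphopeptide() -> ModifiedPeptide:
    """The worked-example phosphopeptide: VLVDQTT(ph)GLSR, phospho on T7."""
    return ModifiedPeptide(FIG_PEPTIDE, ((7, PHOSPHO),))


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def noiseless_spectrum(pep: ModifiedPeptide, charge: int = 2,
                       max_fragment_charge: int = 1) -> Spectrum:
    """Spectrum containing exactly the primary singly charged b/y ladder."""
    ions = [i for i in ion_series(pep, max_fragment_charge)
            if i.series in "by" and i.loss_state == "none"]
    return Spectrum(
        precursor_mz=precursor_mz(pep, charge),
        precursor_charge=charge,
        peaks=tuple((i.mz, 100.0) for i in ions),
        title=pep.label(),
    )


@pytest.fixture
def fig_noiseless_spectrum(fig_phosphopeptide) -> Spectrum:
    return noiseless_spectrum(fig_phosphopeptide)
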