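"""Seeded generator of ion-trap-like phosphopeptide CID spectra.

Two acquisition regimes are emulated:

* **MSA** (multistage activation / pseudo-MS3): one merged spectrum
  carrying the primary b/y ladders, their −H3PO4 satellites, the
  dehydro-residue ladders of the phosphate-lost peptide, the dominant
  precursor −98/z neutral-loss peak, dropout and uniform noise.
* **DDNLMS3** (data-dependent neutral-loss MS3): an MS2 spectrum (primary
  ladders plus a dominant precursor −98/z peak) and a separate MS3
  spectrum of the neutral-loss product containing only the dehydro-ladder
  fragments — the isolation step that costs DDNLMS3 the primary-ion
  information MSA keeps.

Fragment intensities are log-normal draws; peak m/z values carry
Gaussian jitter. Everything is driven by one integer seed and is
byte-reproducible.

The enrichment-scenario fixtures (SIMAC / TiO2 / IMAC) encode only which
peptides of the studied kinases (HuR, p38, and the Chain-B complex) each
resin recovered — no enrichment chemistry is simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fragments import dehydro_ion_series, ion_series
from .masschem import H3PO4, PHOSPHO, ModifiedPeptide, precursor_mz
from .matching import Spectrum

__all__ = ["SimulationConfig", "simulate", "TABLE_PEPTIDES", "SCENARIOS",
           "Fixture", "make_fixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum generator; defaults are the package's
    reference ion-trap conditions."""

    seed: int = 0
    regime: str = "MSA"  # "MSA" | "DDNLMS3"
    dropout_prob: float = 0.0
    noise_peaks: int = 20
    noise_intensity_range: tuple[float, float] = (5.0, 50.0)
    base_intensity_mean: float = 1000.0  # log-normal median of fragment peaks
    base_intensity_sigma: float = 0.4  # log-normal shape
    satellite_intensity_scale: float = 0.6  # −H3PO4 satellites vs primary
    dehydro_intensity_scale: float = 0.5  # dehydro-ladder vs primary
    precursor_NL_intensity: float = 1.5  # × strongest fragment (MSA)
    ms2_NL_dominance: float = 5.0  # × strongest fragment (DDNLMS3-MS2)
    mass_jitter_sd: float = 0.05  # Da
    precursor_ppm_sd: float = 2.0  # precursor mass-error spread

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.regime not in ("MSA", "DDNLMS3"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")


def _draw_peaks(rng, ions, scale_of, cfg: SimulationConfig,
                dropout: bool) -> list[tuple[float, float]]:
    peaks = []
    for ion in ions:
        if dropout and rng.random() < cfg.dropout_prob:
            continue
        inten = cfg.base_intensity_mean * float(
            np.exp(rng.normal(0.0, cfg.base_intensity_sigma))
        ) * scale_of(ion)
        mz = ion.mz + rng.normal(0.0, cfg.mass_jitter_sd) \
            if cfg.mass_jitter_sd > 0 else ion.mz
        peaks.append((mz, inten))
    return peaks


def _finish(rng, peaks, cfg: SimulationConfig, precursor: float, charge: int,
            title: str, provenance: str) -> Spectrum:
    if cfg.noise_peaks and peaks:
        hi = max(m for m, _ in peaks) * 1.05
        for _ in range(cfg.noise_peaks):
            peaks.append((
                float(rng.uniform(100.0, hi)),
                float(rng.uniform(*cfg.noise_intensity_range)),
            ))
    # merge coincident peaks (satellite vs dehydro ladder overlaps)
    peaks.sort()
    merged: list[tuple[float, float]] = []
    for m, i in peaks:
        if merged and m - merged[-1][0] < 0.005:
            merged[-1] = (merged[-1][0], merged[-1][1] + i)
        else:
            merged.append((m, i))
    return Spectrum(precursor_mz=precursor, precursor_charge=charge,
                    peaks=tuple(merged), title=title, provenance=provenance)


def simulate(
    pep: ModifiedPeptide, charge: int, cfg: SimulationConfig,
    title: str = "",
) -> list[Spectrum]:
    """Generate the spectrum (MSA) or spectrum pair (DDNLMS3) for one
    peptide at one precursor charge, reproducibly from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    max_z = max(1, charge - 1)
    title = title or pep.label()

    prec_mz = precursor_mz(pep, charge)
    obs_prec = prec_mz * (1.0 + rng.normal(0.0, cfg.precursor_ppm_sd) * 1e-6)
    st_sites = pep.phospho_st_positions

    primary = [i for i in ion_series(pep, max_z, precursor_charge=None)
               if i.loss_state == "none" or i.series == "immonium"]
    satellites = [i for i in ion_series(pep, max_z, precursor_charge=None)
                  if i.loss_state == "minus_H3PO4"]
    dehydro = (
        [i for i in dehydro_ion_series(pep, st_sites, max_z)
         if i.loss_state == "none"]
        if st_sites else []
    )

    def scaled(scale):
        return lambda ion: scale

    if cfg.regime == "MSA":
        peaks = _draw_peaks(rng, primary, scaled(1.0), cfg, dropout=True)
        peaks += _draw_peaks(rng, satellites,
                             scaled(cfg.satellite_intensity_scale), cfg, True)
        peaks += _draw_peaks(
            rng, [i for i in dehydro if i.contains_dehydro],
            scaled(cfg.dehydro_intensity_scale), cfg, True)
        if st_sites and peaks:
            nl_mz = prec_mz - H3PO4 / charge \
                + rng.normal(0.0, cfg.mass_jitter_sd)
            nl_int = cfg.precursor_NL_intensity * max(i for _, i in peaks)
            peaks.append((nl_mz, nl_int))
        return [_finish(rng, peaks, cfg, obs_prec, charge, title, "MSA")]

    # DDNLMS3: MS2 + MS3 of the neutral-loss product
    ms2_peaks = _draw_peaks(rng, primary, scaled(1.0), cfg, dropout=True)
    if st_sites and ms2_peaks:
        nl_mz = prec_mz - H3PO4 / charge + rng.normal(0.0, cfg.mass_jitter_sd)
        nl_int = cfg.ms2_NL_dominance * max(i for _, i in ms2_peaks)
        ms2_peaks.append((nl_mz, nl_int))
    ms2 = _finish(rng, ms2_peaks, cfg, obs_prec, charge, title + " [MS2]",
                  "MS2")
    if not st_sites:
        warnings.warn(
            f"DDNLMS3 requested for {pep.label()} without phospho-S/T; "
            "MS3 scan is empty"
        )
        ms3 = Spectrum(precursor_mz=obs_prec, precursor_charge=charge,
                       peaks=(), title=title + " [MS3]", provenance="MS3")
        return [ms2, ms3]
    ms3_peaks = _draw_peaks(rng, dehydro, scaled(1.0), cfg, dropout=True)
    ms3 = _finish(rng, ms3_peaks, cfg, obs_prec - H3PO4 / charge, charge,
                  title + " [MS3]", "MS3")
    return [ms2, ms3]


# ---------------------------------------------------------------------------
# Scenario fixtures: the six validated phosphopeptides of the studied
# kinases and which enrichment resin recovered which.

@dataclass(frozen=True)
class RosterEntry:
    sequence: str
    phospho_position: int
    protein: str
    charge: int = 2

    def peptide(self) -> ModifiedPeptide:
        return ModifiedPeptide(self.sequence,
                               ((self.phospho_position, PHOSPHO),))


HUR = "HuR RNA binding protein gi|1022961"
CHAIN_B = "Chain B Appbp1-Uba3-NEDD8 complex gi|126031226"
P38 = "p38 MAP kinase gi|1469306"

TABLE_PEPTIDES: tuple[RosterEntry, ...] = (
    RosterEntry("DVEDMFSR", 7, HUR),
    RosterEntry("VLVDQTTGLSR", 7, HUR),
    RosterEntry("DANLYISGLPR", 7, HUR),
    RosterEntry("SLFSSIGEVESAK", 11, HUR),
    RosterEntry("TAVINAASGR", 1, CHAIN_B),
    RosterEntry("DLSSIFR", 3, P38),
)

_SUBSETS = {
    "SIMAC": tuple(e.sequence for e in TABLE_PEPTIDES),
    "TiO2": ("VLVDQTTGLSR", "SLFSSIGEVESAK", "DVEDMFSR", "DLSSIFR"),
    "IMAC": ("VLVDQTTGLSR", "SLFSSIGEVESAK"),
}

SCENARIOS = ("SIMAC_MSA", "TiO2_MSA", "IMAC_MSA", "SIMAC_DDNLMS3")


@dataclass(frozen=True)
class Fixture:
    scenario: str
    items: tuple[tuple[ModifiedPeptide, Spectrum], ...]
    proteins: tuple[str, ...]
    identifications: pd.DataFrame


def make_fixture(scenario: str, seed: int = 0,
                 cfg: SimulationConfig | None = None) -> Fixture:
    """Build the spectra + identification table for one enrichment
    scenario: the resin's phosphopeptide subset plus six unmodified decoy
    peptides from the same tryptic digests.

    For DDNLMS3 scenarios the MS2 scan of each pair is the one offered to
    the identification pipeline (the MS3 scan is available through
    :func:`simulate`).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {SCENARIOS}")
    resin, regime = scenario.rsplit("_", 1)
    if cfg is None:
        cfg = SimulationConfig()
    cfg = replace(cfg, regime=regime)

    wanted = _SUBSETS[resin]
    entries = [e for e in TABLE_PEPTIDES if e.sequence in wanted]

    items: list[tuple[ModifiedPeptide, Spectrum]] = []
    proteins: list[str] = []
    rows = []
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=64)
    k = 0
    for entry in entries:
        pep = entry.peptide()
        sub = replace(cfg, seed=int(child[k])); k += 1
        spectra = simulate(pep, entry.charge, sub, title=f"{scenario}:{pep.label()}")
        spec = spectra[0]  # MSA merged scan, or the DDNLMS3 MS2 scan
        items.append((pep, spec))
        proteins.append(entry.protein)
        rows.append({
            "title": spec.title, "sequence": pep.sequence,
            "mods": f"Phospho@{entry.phospho_position}",
            "charge": entry.charge, "protein": entry.protein,
            "scenario": scenario,
        })
    # decoys: the same tryptic peptides, unmodified (regime MSA mechanics
    # still apply; with no phospho there is no NL peak or dehydro ladder)
    for entry in TABLE_PEPTIDES:
        pep = ModifiedPeptide(entry.sequence)
        sub = replace(cfg, seed=int(child[k]), regime="MSA"); k += 1
        spec = simulate(pep, entry.charge, sub,
                        title=f"{scenario}:decoy:{entry.sequence}")[0]
        items.append((pep, spec))
        proteins.append(entry.protein)
        rows.append({
            "title": spec.title, "sequence": pep.sequence, "mods": "",
            "charge": entry.charge, "protein": entry.protein,
            "scenario": scenario,
        })
    return Fixture(
        scenario=scenario,
        items=tuple(items),
        proteins=tuple(proteins),
        identifications=pd.DataFrame(rows),
    )
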