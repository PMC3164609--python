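# phosphoval

Phosphopeptide identification, rule-based validation and phospho-site
localization for ion-trap CID data — with a seeded simulator of MSA and
neutral-loss-MS3 spectra to exercise the whole pipeline end to end.

## The problem

Phosphopeptides fragment poorly under collision-induced dissociation
(CID): phospho-Ser/Thr peptides preferentially shed phosphoric acid
(H₃PO₄, −97.9769 Da) instead of breaking the backbone, so MS/MS spectra
are dominated by the precursor −98/z neutral-loss peak and starved of
sequence ions. Instruments work around this either by **multistage
activation (MSA)** — re-activating the neutral-loss product without an
isolation step, yielding one merged spectrum of MS2 and MS3 fragments —
or by **data-dependent neutral-loss MS3 (DDNLMS3)** — isolating the
−98/z product and fragmenting it in a separate scan. Identifications
from such spectra are then held to manual-validation criteria before a
phosphorylation site is believed.

`phosphoval` makes that manual workflow executable and auditable, for
anyone studying individual phosphorylated kinases (e.g. p38 and the HuR
RNA-binding protein) rather than whole phosphoproteomes:

* **masschem / digestion** — monoisotopic mass bookkeeping with a
  configurable modification registry (carbamidomethyl-C fixed;
  oxidation-M, protein N-terminal acetyl, phospho-STY variable), and
  tryptic in-silico digestion with missed cleavages and full-specificity
  bookkeeping (two missed cleavages by default).
* **fragments** — theoretical b/y ladders with −H₃PO₄ satellites,
  dehydro-residue ladders (phospho-Ser → dehydroalanine, phospho-Thr →
  dehydro-2-aminobutyric acid), the precursor neutral-loss product and
  the ~216.04 Th phospho-Tyr immonium marker.
* **matching** — deterministic nearest-Δ peak assignment within 0.5 Da
  (10 ppm precursor), consecutive-run statistics, and a binomial-tail
  identification score.
* **validation** — the acceptance rule engine: score > 20; at least four
  consecutive y- **and** b-ions on abundant signals; special cases for
  protein-C-terminal peptides and R…K missed-cleavage peptides (b-ions
  only); mandatory phosphate evidence (precursor neutral loss, dehydro
  fragments, intact phospho fragments, or the pY immonium); proline
  warnings. Every verdict carries a replayable rule trace.
* **localization** — phospho-isoform enumeration and site-determining
  ion counting: the automated form of "which y/b ions pin the site".
* **synthetic** — the seeded spectrum generator and enrichment-scenario
  fixtures (SIMAC / TiO₂ / IMAC peptide subsets plus unmodified decoys).

## Worked example

The classic validation exercise: the HuR tryptic peptide
`VLVDQTTGLSR` phosphorylated on its second threonine (T7).

```python
>>> import phosphoval as pv
>>> pep = pv.ModifiedPeptide("VLVDQTTGLSR", ((7, pv.PHOSPHO),))
>>> print(f"{pv.peptide_neutral_mass(pep):.4f}")
1267.6173
>>> print(f"{pv.neutral_loss_offset(pv.H3PO4, 2):.2f}")
48.99
```

1267.6173 Da is the monoisotopic neutral mass of the phosphopeptide;
48.99 Th is the spacing at which its doubly charged precursor's
neutral-loss peak appears — the trigger an ion trap watches for.

Localizing the site from a spectrum and running the full pipeline:

```
$ phosphoval pipeline --scenario SIMAC_MSA --seed 1 --out-dir out
SIMAC_MSA: accepted 6 distinct phosphopeptides from 3 proteins; site table -> out/sites.tsv

$ cat out/sites.tsv
sequence        assigned_sites  margin  ambiguous
DVEDMFSR        S7      0       False
VLVDQTTGLSR     T7      3       False
DANLYISGLPR     S7      20      False
SLFSSIGEVESAK   S11     20      False
TAVINAASGR      T1      23      False
DLSSIFR S3      3       False
```

Six phosphopeptides (four from HuR, one from the Chain-B
ubiquitin-activation complex, one from p38 MAP kinase) are accepted
while the six unmodified decoy peptides contribute nothing to the
phosphopeptide count; every site lands on its planted residue. For
`VLVDQTTGLSR` the diagnostic ions include y5 (phospho-carrying) and b7
— the pair that discriminates T7 from the competing T6 and S10
isoforms. The `margin` column is the diagnostic-ion count separating
the best isoform from the runner-up (0 for `DVEDMFSR`, which has a
single candidate site and therefore no competitor).

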