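# Methods

## Mass model

All arithmetic is monoisotopic. The residue table carries the 20
standard residues at 5 decimal places; constants: water 18.010565 Da,
proton 1.00728 Da, CO 27.994915 Da, H₃PO₄ 97.976896 Da, HPO₃
79.966331 Da. Phosphorylation is modelled as +HPO₃ (+79.96633 Da) on
S/T/Y; the CID neutral loss is H₃PO₄, i.e. gas-phase β-elimination
takes one water from the backbone along with the phosphate, leaving
dehydroalanine (from pSer) or dehydro-2-aminobutyric acid (from pThr),
each the residue mass minus water. Phospho-Tyr cannot β-eliminate, so
pY fragments keep their phosphate and the evidence for pY is the
~216.042 Th immonium ion plus intact-pY fragments. The computed pY
immonium (216.042 Th) is commonly quoted rounded as 216.05; all
immonium comparisons therefore carry ±0.02 Th.

The default modification registry is carbamidomethyl-C (fixed,
+57.02146), oxidation-M (+15.99491), protein-N-terminal acetyl
(+42.01057, only permitted on protein-N-terminal peptides) and
phospho-STY (+79.96633). The registry is serializable through the flat
key-value config format, so search spaces are reconfigurable without
code changes.

## Digestion

Sequential Lys-C + trypsin digestion is modelled as a single trypsin
digestion (cleave after K/R): Lys-C sites are a subset of trypsin
sites, so the two-enzyme protocol changes digestion efficiency in the
lab but not the peptide space in silico. Cleavage before proline is
suppressed by default (the standard trypsin rule) and can be switched
off. Peptides are enumerated for 0..max missed cleavages (default 2)
with 1-based parent coordinates and flanking-residue context; full
tryptic specificity checks both termini, with the protein C-terminus
accepted as a valid C-terminal boundary — the population the
validation engine's first special case exists for.

## Fragment chemistry

For a peptide at precursor charge z the theoretical set contains
b1..b(n−1) and y1..y(n−1) at fragment charges 1..max(1, z−1) (the
ion-trap convention), a −H₃PO₄ satellite for every fragment containing
phospho-S/T, the precursor and its −H₃PO₄ product, optional −H₂O/−NH₃
satellites (off by default), and the dehydro ladders of the
phosphate-lost peptide. a/c/z ions are not generated: the model is
CID, not ETD. Complementarity (b_i + y_{n−i} = M + 2·proton at 1 Da
charge) holds to 1e−4 Da by construction and is property-tested.

## Matching and score

Peak assignment is greedy nearest-Δ within the fragment tolerance
(default 0.5 Da), each peak and each theoretical ion used at most
once; exact |Δ| ties prefer the primary (no-loss) ion. Because
candidates are processed in |Δ| order, shrinking the tolerance can
only remove assignments — the candidate list under a tighter tolerance
is a prefix of the looser one. A backbone position counts as matched
if its primary ion or any loss satellite matched; "abundant" means
intensity ≥ 5% of the base peak (the threshold is configuration, and
surfaced in every report, because "abundant signal" must be
automatable to be auditable).

The identification score is −10·log₁₀ of the binomial tail
probability of observing at least the matched number of ions among the
theoretical set, with the per-ion chance-match probability estimated
from the peak count and the tolerance-window width over the observed
m/z span. It is deterministic plumbing, not a calibrated search-engine
score; an externally supplied score can be substituted per
identification, keeping the rule engine engine-agnostic.

## Validation rules

Applied in order, each recorded as (rule, outcome, evidence):

* **R1** score > 20 (default).
* **R2** runs of ≥ 4 consecutive b-ions AND ≥ 4 consecutive y-ions on
  abundant signals. The "both series" reading is the default because
  the special cases below explicitly weaken to b-only — which would be
  meaningless if the general rule demanded only one series. A config
  switch (`consecutive_rule_mode = either`) relaxes it.
* **R3** a peptide lacking C-terminal K/R because it sits at the
  protein C-terminus is accepted on the b-run alone.
* **R4** a peptide with C-terminal Lys and N-terminal Arg (missed
  cleavage) is accepted on the b-run alone.
* **R5** claimed phospho-S/T requires ≥ 1 phosphate fingerprint:
  precursor −98/z neutral-loss peak, matched dehydro fragments
  (−H₃PO₄ fragment satellites count as dehydro evidence — the two are
  the same chemical species), or matched intact-phospho fragments.
* **R6** claimed phospho-Tyr requires the pY immonium ion (±0.02 Th)
  or matched intact-pY fragments.
* **R7** proline-containing peptides are flagged, never rejected:
  proline-directed fragments give intense signals that can suppress
  the rest of the spectrum, which is a reason to look harder, not a
  rejection criterion.

Accepted = R1 ∧ (R2 ∨ R3 ∨ R4) ∧ R5 ∧ R6. Verdicts are monotone in
evidence: adding matched ions can only add runs and fingerprints.
Precursor mass error (ppm) is a report column, not a rule — on
synthetic data it is generator-controlled and carries no information.

## Localization

All placements of the claimed number of phosphates over the S/T/Y
sites are enumerated (C(sites, n) isoforms). An ion is
*site-determining* for an isoform if its m/z differs by more than the
fragment tolerance from the corresponding ion of at least one
competing isoform, or exists for no competing isoform (loss satellites
exist only where the fragment carries phospho-S/T). The isoform score
is the count of its matched site-determining ions; the margin is the
count difference between best and runner-up, and a zero margin is
reported as ambiguous with all tied isoforms listed. The plumbing
score only decides which count-tied isoform is listed first. This is a
deliberate mirror of manual diagnostic-ion reasoning — a deterministic
count, not an Ascore/PhosphoRS-style probability. The reported
diagnostic ions are the best isoform's matched site-determining ions
(those separating it from *any* competitor, not just the runner-up):
for VLVDQTT(ph)GLSR that set contains both y5 (separating T7 from T6)
and b7 (separating T7 from S10), and no single pairwise comparison
yields both.

## Synthetic spectra

The generator emulates LTQ-style ion-trap CID of phosphopeptides, in
arbitrary intensity units:

* fragment intensities log-normal (median 1000, σ = 0.4) — a
  right-skewed abundance spread without the extreme dynamic range that
  would defeat a fixed abundance floor;
* −H₃PO₄ satellites at 0.6× and dehydro-ladder fragments at 0.5× the
  primary intensity scale;
* the precursor −98/z peak at 1.5× the strongest fragment in MSA and
  5× in the DDNLMS3 MS2 scan — the neutral-loss dominance that
  motivates MS3 acquisition in the first place;
* Gaussian m/z jitter of 0.05 Da (well inside the 0.5 Da matching
  tolerance, as for a real ion trap), precursor mass error drawn at
  2 ppm s.d.;
* per-peak Bernoulli dropout (default 0 for fixtures) and uniform
  noise peaks (default 20 per spectrum, intensity 5–50).

MSA produces one merged spectrum (primary ladders + satellites +
dehydro ladders + precursor NL). DDNLMS3 produces an MS2 scan (primary
ladders + dominant NL peak) and an MS3 scan of the neutral-loss
product (dehydro ladders only) — reproducing the regime difference
that MSA retains primary-ion information the MS3 isolation step
discards. Everything is driven by one integer seed and byte-stable.

The scenario fixtures encode only *which* peptides each enrichment
resin recovered from the studied kinases (SIMAC: all six; TiO₂: four;
IMAC: two), plus six unmodified decoy peptides from the same tryptic
digests; no enrichment chemistry is simulated, so resin differences
are labels, not predictions. What passing tests show is therefore that
the pipeline's logic is correct on spectra with the stated noise,
dropout and jitter structure — not that it would survive co-eluting
chimeric spectra, isotope envelopes, charge-reduced species, or
retention-time effects, none of which the generator models.

## Problem sizes and numerical choices

Property suites run at: ≥ 1000 random peptides for mass/complementarity
invariants; 200 seeded trials of random 8–12-mers (≥ 2 S/T sites,
planted single phospho, dropout 0.3, 20 noise peaks) for planted-site
recovery, asserted ≥ 95%; 100 paired replicates for the MSA-vs-DDNLMS3
matched-position comparison; all scenarios at zero dropout for the
generator/validator round trip. Coincident generator peaks (< 0.005 Th
apart, e.g. a −H₃PO₄ satellite and the identical-mass dehydro
fragment) are merged by intensity summation. Ties are broken
deterministically throughout (smaller |Δ|, then primary ion; isoform
order by count, plumbing score, then position).

## Known limitations

No intensity prediction or mobile-proton modelling; no semi-tryptic
searches; no FDR estimation (the decoys exist to give the rule engine
something to reject, not to calibrate error rates); no multi-spectrum
aggregation of site evidence; no ETD/ECD evidence rules. The plumbing
score is not comparable across instruments or to any search engine's
scale — the threshold of 20 is meaningful only relative to this
score's null behaviour, where random spectra score near zero.
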