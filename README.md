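# haptenfit

Hapten-density determination for peptide–carrier conjugate vaccines from
linear-MALDI mass spectra.

Conjugating synthetic epitope peptides onto an immunogenic carrier protein
(e.g. CRM197, a ~58 kDa non-toxic diphtheria-toxin mutant) turns a pure
protein into a mixture of species carrying 0, 1, 2, … peptides. How many
peptides end up on an average carrier — the **hapten density (HD)** — and
how broadly that number is spread — the **dispersity (σ)** — are the key
quality attributes of such a conjugate: they drive immunogenicity and
batch-to-batch consistency, yet SDS-PAGE and SEC only show an unresolved
smear. `haptenfit` is for vaccine and bioconjugate developers who want
those numbers from a MALDI-TOF spectrum.

## The method

In a linear-MALDI spectrum the conjugate appears as a ladder of peaks: the
species with peptide load *n* (at charge *z*, mainly *z* = 2 for a ~58 kDa
carrier) is centred at

```
c(n) = (M0 + n·Δ + z·m_p) / z ,      m_p = 1.007276 Da
```

where `M0` is the load-0 mass and `Δ` the neutral mass gained per peptide
(peptide mass + crosslinker remnant, ~1835 Da for a single-repeat IRIS
peptide coupled through SBAP). The pipeline is

1. **read / calibrate** — mzML or two-column text; polynomial m/z
   correction against calibrant ions (e.g. multiply charged BSA);
2. **preprocess** — Savitzky–Golay smoothing, SNIP baseline estimation and
   subtraction;
3. **deconvolute** — fit the whole ladder jointly as a sum of Gaussians
   whose centres are pinned to `c(n)` up to a bounded common shift and tiny
   per-peak jitter, with non-negative amplitudes; fit quality is the
   adjusted R² of the cumulative fit;
4. **report** — with `VUC_n` the fitted Gaussian area of load *n*:

```
HD = Σ (VUC_n · n) / Σ VUC_n          σ = sqrt( Σ VUC_n (n − HD)² / Σ VUC_n )
```

A simulator renders spectra with known ground truth (analytic binomial /
Poisson / explicit load distributions, exponential baseline, seeded noise),
and design utilities compute peptide masses, ladder spacings and epitope
identities.

## Worked example

```python
from haptenfit import ConjugateLadder, SimulationConfig
from haptenfit.pipeline import estimate_hapten_density
from haptenfit.simulate import simulate_spectrum

for p in (0.1, 0.2, 0.35):          # site occupancy ~ increasing molar excess
    cfg = SimulationConfig(p=p, seed=1)
    spectrum, truth = simulate_spectrum(cfg)
    ladder = ConjugateLadder(M0=cfg.carrier_mass, delta=cfg.delta,
                             z=2, n_min=0, n_max=20)
    rep, _ = estimate_hapten_density(spectrum, ladder)
    print(f"p={p}: true HD={truth.true_hd:.2f}  ->  {rep.summary()}")
```

prints

```
p=0.1: true HD=2.00  ->  HD=1.995 sigma=1.368 adjR2=0.99845
p=0.2: true HD=4.00  ->  HD=3.937 sigma=1.796 adjR2=0.99848
p=0.35: true HD=7.00  ->  HD=6.874 sigma=2.174 adjR2=0.99836
```

i.e. the estimated hapten density tracks the true mean load within ±0.15
peptides, dispersity follows the binomial SD, and every cumulative fit has
adjusted R² above 0.99. The same run is available from the shell
(`haptenfit simulate`, `haptenfit fit`; see `haptenfit --help`).

The design utilities work on plain FASTA. For the three IRIS epitope
homologs (the 13-residue IL-17RB inactivation site, residues 19–31):

```
$ haptenfit design iris.fasta
name    avg_mass  mono_mass  ladder_delta
bIRIS   1751.98   1750.88    1863.08
mIRIS   1723.92   1722.84    1835.02
hIRIS   1763.99   1762.87    1875.09
identity matrix (%):
        bIRIS   mIRIS   hIRIS
bIRIS   100.0   92.3    69.2
mIRIS   92.3    100.0   76.9
hIRIS   69.2    76.9    100.0
```

Masses are for the synthesized conjugate peptides
(Ac-epitope-GG-Cys, free acid); `ladder_delta` adds the SBAP crosslinker
remnant (111.10 Da) — the mass step between neighbouring ladder peaks
times the charge.

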