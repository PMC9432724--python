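# mitoloc

A stochastic simulator of co-translational mRNA localization to
mitochondria in budding yeast.

Many nuclear-encoded mitochondrial mRNAs localize to the mitochondrial
surface while they are being translated: once a ribosome has translated the
amino-terminal **mitochondrial targeting sequence (MTS)** of the nascent
peptide, the exposed MTS can tether the whole mRNA–ribosome complex to
import receptors on the outer membrane.  Some of these transcripts localize
*constitutively*; others localize *conditionally*, only when mitochondria
occupy a larger share of the cell (respiratory growth) or when elongation
is frozen with cycloheximide (CHX).  `mitoloc` is for quantitative cell
biologists and biophysicists who want to ask how far translation kinetics
alone — initiation rate, elongation rate, transcript length, and a
maturation delay before a translated MTS becomes binding-competent — can
explain that difference, without invoking mRNA-specific binding proteins.

## The model

Each mRNA is simulated from synthesis to decay:

* **Translation** — ribosomes initiate at rate *k*<sub>init</sub> when the
  first codon is free, advance codon-by-codon at *k*<sub>elong</sub> under
  exclusion, and terminate from codon *L*.  A ribosome past codon
  *l*<sub>MTS</sub> = 100 carries a fully translated MTS; in the maturation
  model that MTS becomes binding-competent after an exponential delay with
  mean τ<sub>MTS</sub> = 1/*k*<sub>MTS</sub>.  The mRNA decays at
  *k*<sub>decay</sub> = 0.0017 s⁻¹.  Simulation is exact (Gillespie).
* **Transport** — the cytosol around a mitochondrial tubule is a set of
  concentric cylinders: a binding shell (*r*<sub>m</sub> < *r* <
  *r*<sub>m</sub> + 25 nm), an imaging shell (up to *r*<sub>m</sub> +
  250 nm), and bulk cytosol out to a reflecting wall at
  *R* = *r*<sub>m</sub>/√(*f*<sub>m</sub>/0.8) that encodes the
  mitochondrial volume fraction *f*<sub>m</sub>.  Region-to-region moves
  are sampled with an event-driven propagator: exact first-passage times
  and splitting probabilities of 2-D radial diffusion (Bessel-eigenfunction
  expansions), validated against a brute-force SDE integrator.
* **Binding** — a competent mRNA entering the binding shell binds
  instantly and stays bound until its last competent MTS terminates.
  Irreversible binding breaks detailed balance, so localization depends on
  the *rates* of competence switching and diffusive search, not just their
  equilibrium ratios.

Closed-form predictors accompany the simulator: the mean number of
translated MTSs per mRNA
β = *k*<sub>init</sub>(*L* − *l*<sub>MTS</sub>)/*k*<sub>elong</sub>, its
maturation-corrected analogue β<sub>mature</sub>, the mean competent
exposure time per MTS, and the mean diffusive search time to an absorbing
cylinder.  A four-state Markov model (competent × proximal) gives the
analytic rapid- and slow-transport limits, and a calibration module
estimates per-gene (*k*<sub>init</sub>, *k*<sub>elong</sub>) from relative
protein-per-mRNA and ribosome-occupancy measurements anchored on *TIM50*.

## Worked example

The typical conditional gene (*L* = 393, *k*<sub>init</sub> = 0.3253 s⁻¹,
*k*<sub>elong</sub> = 14.5086 aa/s) with a 40 s MTS maturation time:

```sh
$ mitoloc closedform --name conditional-median --k-init 0.3253 \
      --k-elong 14.5086 -L 393 --tau-mts 40
name	beta	beta_mature	t_expo	t_expo_mature	t_search
conditional-median	6.56940711	1.411219249	20.19491888	3.66741588	9.557833131
```

Without maturation the gene would carry β ≈ 6.6 exposed MTSs, each exposed
for ~20 s — it would localize under any condition.  A 40 s maturation time
cuts that to β<sub>mature</sub> ≈ 1.4 competent MTSs exposed for ~3.7 s,
*shorter* than the ~9.6 s diffusive search time at 4% mitochondrial volume
fraction: localization becomes switch-like in the volume fraction.  The
full simulation quantifies it:

```python
from mitoloc import (GeneKinetics, CompetenceModel, SimulationConfig,
                     geometry_from_mvf, simulate_ensemble,
                     ensemble_localization, ensemble_chx_localization)

gene = GeneKinetics("conditional_median", k_init=0.3253, k_elong=14.5086, L=393)
cfg = SimulationConfig(gene=gene, competence=CompetenceModel.maturation(40.0),
                       geometry=geometry_from_mvf(0.04), seed=1)
records = simulate_ensemble(cfg)   # 50 mRNA lifetimes
print(f"binding localization: {ensemble_localization(records, 'binding'):.3f}")
print(f"imaging localization: {ensemble_localization(records, 'imaging'):.3f}")
print(f"CHX localization:     {ensemble_chx_localization(records):.3f}")
```

prints

```
binding localization: 0.488
imaging localization: 0.527
CHX localization:     0.883
```

Half the lifetime is spent within binding range, but arresting elongation
(CHX leaves every translated MTS exposed) nearly doubles it — the
signature of a conditional transcript.  Re-running with the constitutive
median parameters (*L* = 483, *k*<sub>init</sub> = 0.1259,
*k*<sub>elong</sub> = 7.7468) gives high localization with a much smaller
CHX response.  `mitoloc sweep --axis mvf ...` and `mitoloc simulate`
expose the same machinery from the shell, and `mitoloc fourstate`,
`mitoloc rates` and `mitoloc synth` cover the analytic model, the rate
estimation and the synthetic cohort generator.

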