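# paleocroc

Scaffold-constrained parsimony phylogenetics and phylogenetic body-size
estimation for fossil crocodyliforms.

Large-bodied crocodyliforms such as *Deinosuchus* pose two linked inference
problems.  First, where do fossil taxa attach on a tree whose extant
backbone is known from molecules?  Morphological matrices alone often fail
to recover clades like Longirostres, so fossil placement is done by maximum
parsimony under a *molecular scaffold*: extant relationships are fixed and
only the fossils float.  Second, how large were these animals?  Total body
length (TL) is estimated from head width (HW, the distance across the
quadrates) via an extant allometry with phylogenetically structured
residuals, so that a fossil's prediction borrows strength from its relatives
rather than from a single living proxy species.

`paleocroc` implements that chain as a tested library for phylogeneticists
and vertebrate palaeontologists:

1. **Parsimony** (`paleocroc.parsimony`) — generalized Sankoff tree length
   with unordered (Fitch) and ordered morphocline (Wagner, cost `|i−j|`)
   characters, ambiguity sets and missing data; random-addition + SPR search
   under a backbone constraint; strict and reduced (rogue-pruned) consensus;
   full MPR ancestral-state sets.
2. **Chronology** (`paleocroc.chronology`) — minimum-branch-length (mbl)
   time calibration: node ages are the pointwise-minimal solution of
   *node ≥ oldest descendant tip* and *parent ≥ child + m* with tips fixed
   at their first-appearance ages.
3. **Allometry** (`paleocroc.allometry`) — log₁₀ TL = β₀ + β₁ log₁₀ HW fitted
   by OLS or PGLS under Brownian covariance with Pagel's λ; fossil TL imputed
   by a Gibbs sampler whose draws combine the conjugate coefficient/variance
   conditionals with the Brownian kriging conditional
   `x_f β + C_fo C_oo⁻¹ (y − Xβ)`.
4. **Size evolution** (`paleocroc.size_evolution`) — the four size classes
   (small ≤ 1.5 m < medium ≤ 4 m < large ≤ 7 m < gigantic), 50-cm bins for
   ancestral-state plotting, ordered-parsimony ASR of bins, Fitch ASR of
   binary osmoregulation (salt-tolerant vs freshwater), and bin-to-bin
   reduction percentages.
5. **Synthetic data** (`paleocroc.synthetic_data`) — birth–death trees with
   fossil tips, Mk-type characters (ordered ones as adjacent-step chains),
   and allometries with known slope/λ/σ², so every stage is testable against
   a known truth.

The `analysis/` directory holds the numbered drivers that run the chain on
the synthetic study-scale dataset (`01_simulate_dataset.py` …
`05_ancestral_size_states.py`), writing tables under `results/`.  A thin CLI
(`paleocroc simulate|search|consensus|calibrate|predict|bin|asr|run-all`)
exposes the same stages.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/02_search_and_consensus.py
python analysis/03_calibrate_timescale.py
python analysis/04_estimate_body_sizes.py
python analysis/05_ancestral_size_states.py
```

prints, among other lines:

```
matrix: 24 taxa x 56 characters (11 ordered, 23% missing)
26 equally best trees of length 212 (generating tree scores 214)
consensus resolution: 17/23 clades; 16/23 true clades recovered
root age: 73.71 Ma
branches: 40, min duration 5.00 Myr (configured minimum 5.0)
PGLS: log10 TL = 1.011 + 0.958 log10 HW (sigma2=0.0007, lambda=0.00; truth slope 0.95, lambda 0.9)
predicted 8 fossils; 95% interval covers the withheld truth for 7/8; median |rel. error| of the mean 7.9%
largest fossil: T018 mean 7.59 m (97.5%: 8.59 m; true 8.39 m)
largest reduction: root 100-150 cm -> 50-100 cm: at least 33%, up to 67%
osmoregulation root MPR: ['saltwater_tolerant'] (10 freshwater-coded tips)
```

Reading this: the search finds trees two steps shorter than the generating
topology (noise plus missing data make that expected), the calibrated tree
honours the 5-Myr branch minimum, the fitted allometry matches the
generating slope, and the largest fossil — a *Deinosuchus*-style giant — has
a predictive mean of 7.59 m with the truth inside the 95% interval.  The
reduction line gives the guaranteed ("at least") and maximal ("up to")
percentage shrinkage between ancestral-state bins, both referenced to the
ancestral bin's upper bound; applied to the published 200–250 cm → 150–200 cm
shrinkage this convention yields 20% and 40%.

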