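# twochain

Predicting heteropolymer phase separation from two-chain contact maps.

## The problem

Solutions of heteropolymers — simple hydrophobic–polar (HP) copolymers or
intrinsically disordered proteins — either *phase separate* into coexisting
dense and dilute phases above a saturation concentration, or merely
*aggregate* into finite clusters at every concentration.  Classical
dilute-solution metrics such as the single-chain radius of gyration Rg and
the pairwise second virial coefficient

B22 = 2π ∫₀^∞ [1 − e^(−u(r)/kBT)] r² dr

(with u(r) the potential of mean force between the centres of mass of two
chains) can fail to distinguish the two behaviours: sequences tuned to
*identical* B22 can still diverge in their phase behaviour.

`twochain` implements a dilute-solution observable that keeps the spatial
information B22 discards: the **interchain contact map**.  Two chains with
the same sequence are sampled in umbrella windows of their centre-of-mass
distance r; decorrelated configurations with r inside the attractive well of
the PMF (u within 1 kBT of its minimum) give a symmetric N×N matrix C whose
entry C_ij is the fraction of configurations with monomer i of one chain
within r_c of monomer j of the other.  Simple statistics of C —

* the mean ⟨C⟩ = Σ C_ij / N²,
* the variance Var(C) = Σ C_ij² / N² − ⟨C⟩²,
* its Fourier split sums S_{≤k†} and S_{>k†} (Parseval: their sum is
  Var(C)), and
* the variance divergence index, the mean squared gap between the
  wavenumber-ordered and power-ordered explained-variance curves —

feed a logistic-regression classifier of phase behaviour whose accuracy is
summarised by the ROC-AUC over randomised 80/20 train–test splits.

The package ships a minimal HP model (Kremer–Grest bead–spring chains; H–H
pairs attract via a truncated-and-shifted Lennard-Jones well of tunable
depth ε/kBT, pairs involving P are purely repulsive WCA), a Metropolis Monte
Carlo sampler, PMF/B22 estimation with honest error propagation, an
ε-matching routine that tunes each sequence to a prescribed B22, the full
contact-map/spectral feature stack, the classifier, and synthetic-fixture
generators for every stage.  Other pairwise models (e.g. residue-level
coarse-grained IDP models) plug in as `(r, type_i, type_j) -> energy`
callables with a declared cutoff, with r_c exposed as a hyperparameter.

## Worked example

```python
from twochain import (HPSequence, ModelParameters, sample_two_chain_pmf,
                      draw_well_configurations, compute_contact_map,
                      contact_stats, compute_b22, power_spectrum,
                      split_sum, ev_curves)

seq = HPSequence("demo", "HHPHHPPHPH")          # N = 10, 60% hydrophobic
params = ModelParameters(epsilon=1.2)           # H-H well depth, in kBT
windows, pmf = sample_two_chain_pmf(seq, params, n_sweeps=5000,
                                    seed=42, r_max=7.0)
b22 = compute_b22(pmf)
well = draw_well_configurations(windows, pmf, 40, seed=43)
cmap = compute_contact_map(well, rc=3.0, sequence_id=seq.id)
stats = contact_stats(cmap)
spec = power_spectrum(cmap)
sf = split_sum(spec, 2.0)
```

prints, via the obvious f-strings:

```
PMF well: [1.45, 3.45] sigma, depth u_min = -1.10 kBT
B22 = -32.7 +/- 93.7 sigma^3
contact map: <C> = 0.707, Var(C) = 0.0121
split sum at k=2: S_leq = 0.0089, S_gt = 0.0033
variance divergence index = 0.00108
```

Reading this: the two chains attract (negative B22, an attractive PMF well
between 1.45 and 3.45 σ), contacts are frequent (⟨C⟩ ≈ 0.71) and their
spatial pattern is dominated by long-wavelength structure (S_{≤2} carries
~73% of Var(C); the near-zero divergence index says the power-ordered and
wavenumber-ordered spectra almost coincide).  The quoted B22 uncertainty is
dominated by the correlated stitching/anchoring drift of the PMF at this
small sampling budget and shrinks with `n_sweeps`.

Given a labelled feature table, the classifier follows the
model/results pattern:

```python
from twochain import PhaseClassifier
model = PhaseClassifier.from_dataframe(df, features=["contact_variance"])
print(model.fit().summary())
ev = model.evaluate_splits(n_splits=185, seed=7)
print(ev)   # EvaluationResult(auc = ... +/- ..., n_splits=185)
```

A command-line interface mirrors the pipeline stages
(`twochain simulate-pmf | b22 | match-b22 | contact-map | spectrum |
features | classify | synth | pipeline`); all stages exchange plain-text
files.

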