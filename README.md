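# nichesignal

Local-scale environmental niche estimation and phylogenetic-signal
analysis for mapped forest plots.

Given a rooted phylogeny, a stem map (tag, species, x, y, life stage)
and a quadrat-level environment table (four topographic and nine soil
variables), the package:

1. reduces the soil variables by PCA and estimates each species' niche
   on every axis as the argmax of the binned conditional occurrence
   probability p(E|x) over quadrats;
2. classifies quadrats into habitats (valley / slope / ridge for k=3)
   from standardized topography and tests species–habitat association
   with torus-translation nulls (all toroidal shifts of the habitat
   map, optionally including its rotated and mirrored variants);
3. quantifies phylogenetic signal with Blomberg's K (tip-shuffle
   permutation test), Sankoff parsimony scores (tip-shuffle null), and
   NRI/NTI (standardized MPD/MNTD against random draws from the species
   pool) for habitat-preference groups;
4. ships a fully ground-truthed synthetic plot generator (pure-birth
   trees, lambda-scaled Brownian niche evolution, Gaussian random
   environment fields, Gaussian niche-response stem placement) so every
   stage can be calibrated without external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the
documented invariants, and `tests/test_acceptance.py` with one test per
acceptance criterion. One acceptance assertion
(`test_criterion_4_torus_oracle_stripe`) is a deliberate known-red: a
full-height column-stripe habitat map is invariant under row-only torus
shifts, so the observed statistic is necessarily tied with 4 of the 25
translation null values and a strict-maximum quantile of 1.0 cannot
occur; the hand-enumeration oracle sub-assertions in the same test (and
in `tests/test_habitat.py`) confirm the implementation matches the
enumerated null exactly.

## Command line

```sh
nichesignal simulate  --seed 1 --out-dir out/sim
nichesignal classify  --env out/sim/environment.tsv --k 3 --out out/habitats.csv
nichesignal associate --stems out/sim/stems.tsv --env out/sim/environment.tsv \
                      --habitat-map out/habitats.csv --out out/assoc.tsv
nichesignal niche     --stems out/sim/stems.tsv --env out/sim/environment.tsv \
                      --stage adult --out out/niches.tsv
nichesignal signal-k       --tree out/sim/tree.nwk --traits traits.csv
nichesignal signal-sankoff --tree out/sim/tree.nwk --states states.csv
nichesignal dispersion     --tree out/sim/tree.nwk --groups groups.csv --out out/disp.tsv
nichesignal run-all   --config config.txt --seed 1 --out-dir out/full
```

`run-all` executes the whole chain (species filters with the default
n ≥ 20 seedlings / n ≥ 100 adults thresholds, habitat classification,
torus tests at alpha 0.025, niche estimation on the 4 topographic + 3
soil-PCA axes, K / Sankoff / NRI–NTI with 999 permutations) and writes
per-stage result tables, a cross-stage table restricted to the species
common to both stages, and a `manifest.json` recording config, seeds
and outputs. Runs are byte-reproducible given config + seed.

Config files are flat `key: value` text; keys prefixed `sim_` configure
the synthetic generator (e.g. `sim_conservatism_lambda: 0.0` for fully
labile niches). See `PipelineConfig` and `SimulationConfig` for the
full key list.

## Conventions

- Coordinates are 0-based metres; quadrat intervals are half-open
  `[low, high)`; quadrat `(row, col)` derives from `(y, x)`.
- The circular aspect variable is consumed as
  `northness = cos(aspect * pi / 180)` wherever a linear axis is
  needed.
- Torus-null quantiles use mean ranks for ties; verdicts are positive
  above `1 - alpha`, negative below `alpha`, per habitat independently.
- All permutation p-values use the add-one rule
  `(1 + r) / (1 + n_perm)`.
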