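# Methods

## Scope and data model

`poxload` models drug solubilization in ABA-triblock pOx/pOzi micelles as a
supervised classification problem over *formulations*: a polymer
(A monomer, B monomer, block lengths `nA1/nB/nA2`, two termini), one or two
drugs, the polymer and drug feeds in g/L, and the time point of the
solubilization measurement in days. The measured endpoint is the solubilized
drug mass per drug, from which loading capacity
`LC = 100·m_sol/(m_sol + m_polymer)` and loading efficiency
`LE = 100·m_sol/m_added` follow. LC assumes the polymer dissolves
completely, which holds for these highly water-soluble carriers below their
cloud point. For coformulations the default LC uses each drug's own
solubilized mass in the drug term; a `total_cargo` switch uses the summed
cargo instead, since the published convention for two-drug LC is ambiguous.

## Component structures

Descriptors are computed per micellar component, never on the full polymer:

- **Capped monomers.** A repeat unit carries two attachment dummies
  (`[*:1]N(C(C)=O)CC[*:2]` for 2-methyl-2-oxazoline). Capping replaces one
  attachment by H and the other by methyl; a backbone-nitrogen attachment is
  always methylated so the capped molecule keeps the tertiary amide pattern
  of the real backbone (2-methyl-2-oxazoline caps to
  N-methyl-N-ethylacetamide). Termini (single attachment) are methyl-capped.
- **Pseudotrimer.** Simplex descriptors need the polymer as one molecule; a
  linear T1–A–B–A–T2 chain containing each building block once serves as a
  proxy. Tetraatomic fragments cannot span more than two adjacent units, so
  the pseudotrimer reproduces every fragment of the real chain; the implicit
  assumption of roughly 2:1 A/B stoichiometry is compensated by the
  molar-fraction weighting.

The monomer registry ships the named pOx/pOzi monomers (MeOx, EtOx, nPrOx,
nBuOx, PentOx, BzOx, PhOx, PhenOx and their oxazine analogues) with methyl
and piperidine termini; registry polymers default to nominal 35/20/35
blocks, the composition of the triblocks used in the underlying
solubilization studies.

## Mixture features

Stoichiometry per polymer chain: `N_total = nA1 + nB + nA2 + 2 + Σ N_drug`,
with fractional drugs per chain
`N_drug = (m_added/m_polymer)·(MW_polymer/MW_drug)`. Drug counts are *not*
rounded — the weighting is continuous in the feed ratio; a
`round_drug_count` flag restores integer behavior for fingerprints.

- `DESC_MIX[d] = Σ_i n_i·DESC_i[d]` (linear molar-fraction combination), with
  sub-mixtures over the A block + termini (`ABLOCK`), the B block (`BBLOCK`)
  and the drugs (`DRUG`) using renormalized fractions.
- `FP_MIX[b] = Σ_i N_i·FP_i[b]` for count fingerprints (ECFP4/6 = Morgan
  radius 2/3, RDKit path 5/7, Avalon at 16 384 bits to limit hash
  collisions, MACCS at its native 167 keys); a `DRUG`-only mixed fingerprint
  is also emitted.
- Experimental features are always appended: feeds, time point, block
  lengths, per-component molar fractions, drugs per chain.

## Descriptor backend

Built on RDKit; the engine id (`backend_id`) records the configuration.
Besides RDKit's standard 2D descriptor set it provides:

- **Chi connectivity indices** (Kier–Hall): sums of `prod(δ_i)^-1/2` over
  connected subgraphs up to 7 edges, classified as path / chain (cyclic) /
  cluster / path-cluster, with sigma (`d`, vertex degree) and valence (`dv`,
  `(Zv−h)/(Z−Zv−1)`) weighting; mordred-style names (`Xp-7dv`, `Xch-6d`,
  ...). Verified against RDKit's `Chi0v`/`Chi1v` and an independent
  path-enumeration oracle.
- **Moreau–Broto autocorrelations** `ATS`/`ATSC` (lags 0–7) over atomic
  number, mass, van-der-Waals volume and Gasteiger charge.
- **3D-MoRSE** descriptors from a single ETKDGv3 conformer (fixed seed,
  default 1853) relaxed with MMFF94s; 32 scattering values per weighting
  block (unweighted, m, v, se, p, i, s — `Mor03p` is the third value of the
  polarizability block). Embedding failures yield missing values, which the
  preprocessing filter removes.
- **SpMAD_Dt** — spectral mean absolute deviation of the detour
  (longest-path) matrix, computed exactly by decomposing the molecule into
  biconnected blocks: the longest simple path between two atoms is the sum of
  block-internal longest paths along the block-cut-tree route (exhaustive DFS
  within each block; molecular ring blocks are small).
- **LogS** — ESOL-style estimate
  `0.16 − 0.63·clogP − 0.0062·MW + 0.066·RB − 0.74·AP`, plus `nRot` and
  `RotRatio`.

## Simplex (SiRMS) descriptors

Atoms are labeled per scheme: element+hybridization (`6>sp2`), or binned
numeric properties with inclusive upper bounds (logp: A ≤ −0.5 < B ≤ 0 <
C ≤ 0.5 < D; mr: 1.5/3/8 — Crippen atomic contributions). Schemes for
externally computed per-atom properties (eeq −0.28/0/0.28, alp 6/9/12,
sa/sdx/sdc 0.5/0.75/1) are plug-ins: the default build computes none of them
and records the omission in the backend id. Vectors are produced with and
without explicit hydrogens (`sirms` / `sirms-noH`).

Every 4-atom subset of a molecule is one simplex, keyed by the label multiset
and the isomorphism class of the induced bond topology (bond orders are not
distinguished). Counting is exact without visiting all C(n,4) subsets:
connected 2/3/4-subgraphs are enumerated; the (3+1), (2+2) and (2+1+1)
disconnected patterns are counted from adjacency complements; the fully
scattered (1+1+1+1) pattern is the per-label-multiset remainder of C(n,4),
so the total is conserved by construction.

For mixtures, single-molecule simplexes (SiRMS-S) are weighted by the
component's molar fraction (the polymer fraction aggregates monomers and
termini). Mixture simplexes (SiRMS-M) combine up to three connected
fragments from 2–3 distinct components — partitions 3+1, 2+2 and 2+1+1,
where the 2+1+1 case may take two disjoint, non-adjacent fragments from one
molecule — and are weighted by twice the smallest molar fraction among the
involved components ("doubled minor fraction"); for three-component
coformulations the minimum extends the published two-component rule.
Intramolecular disconnected simplexes are counted (a connected-only flag
exists for ablation).

## Training pipeline

`ThresholdClassifier(X, y).fit(seed)` produces a results object with the
fitted bundle and a `summary()`:

1. **Preprocessing** (training set only): drop features with any missing
   value; near-zero variance (variance < 1e-12, or dominant/second frequency
   ratio > 19 with < 10 % unique values); pairwise |r| > 0.9 — connected
   correlation clusters keep their lexicographically first member
   (deterministic tie-break); then Yeo-Johnson power transform with
   centering/scaling. Queries are aligned to the fitted columns; absent
   sparse count features are true zeros.
2. **Boruta**: each round duplicates and permutes all features as shadows,
   fits a random forest on [real | shadow], scores a hit when a feature beats
   the best shadow, and confirms/rejects by Bonferroni-corrected binomial
   tests (α = 0.01, 40 rounds). Tentative features are kept by default (a
   permissive reading; switchable).
3. **Repeated stratified CV grid search**: default 5 folds × 20 repeats
   (regression 10 repeats), tune length 20 (XGBoost 5, regression 10/3),
   majority-class downsampling to exactly 1:1 inside every training fold
   (resampled per fold), ROC AUC as the selection metric (decision values
   for margin classifiers). Families: RF, XGBoost, SVC (RBF), Gaussian
   process (RBF), kNN, logistic regression; PLS/linear/SVR/GPR for
   regression. Grids are the backend defaults spanned at the requested tune
   length (the reference tool's exact grids are not published).
4. **Refit** on the downsampled full training set with the best parameters;
   a k-NN applicability domain (below) is fitted on the selected, transformed
   training matrix.

`y_randomize` refits the pipeline on label permutations to estimate the
chance-level metric distribution. Metrics are computed from fold confusion
counts: Sens, Spec, PPV, NPV, balanced accuracy (Sens+Spec)/2, F1, and
nMCC = (MCC+1)/2 ∈ [0,1]; undefined ratios are reported as absent, never as
zero, matching the all-positive null baseline (Sens 1, Spec 0, Acc 0.5,
PPV = prevalence, F1 = 2p/(1+p), nMCC undefined).

## Applicability domain

For each training row, the mean Euclidean distance to its k nearest training
neighbors (self excluded) is computed in the transformed, selected feature
space; `D_cutoff = <D> + z·s` with the sample standard deviation. A query is
in-domain when its own mean k-NN distance is ≤ the cutoff (inclusive).
Defaults k = 5, z = 0.5 — conventional values in the k-NN AD literature; the
published study does not print its k and z, so both are configurable and
stored in the bundle.

## Prediction and screening

Out-of-domain threshold predictions count as negative. Each ladder
(LC 10/20/30/40, LE 20/40/60/80) is walked in ascending order, stopping
after two consecutive failures; the estimate is one point below the rung
above the last pass (LE 39 % when passing LE20 but not LE40), 0 when nothing
passed, and the threshold value itself — flagged as a "≥" lower bound — when
the top rung passed (the interior rule does not define this case; the
conservative bound was chosen). Masses: `m_LE = LE/100·DF`,
`m_LC = (LC/100)·P/(1 − LC/100)` (LC = 100 % cannot be inverted and raises),
combined = mean. Screening defaults: 10 g/L polymer, 6 g/L drug feed, 0-day
measurement, a five-polymer panel covering the most common B blocks, rows
sorted by thresholds passed; an optional prefilter drops drugs whose
ESOL-estimated aqueous solubility is ≥ 10 g/L (poorly soluble compounds are
the intended use case; the original external solubility service is replaced
by the backend's own estimate).

## Synthetic data

The generator emulates the schema and qualitative signal structure of a real
formulation database: ~30 real hydrophobic drugs (shipped SMILES), six B
monomer types, block lengths from 20/10/20 to 35/20/35, drug feeds 2–12 g/L
at 10 g/L polymer, time points 0–180 days, 10 % coformulations. The planted
rule is additive-logistic in interpretable properties — drug H-bond-donor
count, a mid-logP window, B-block length, and a negative drug-feed term —
attenuated exponentially in storage time (decay 0.004/day) with Gaussian
noise (sd 0.05) and clamping to [0, m_added]. It reproduces the signs real
data show (feed/LE anticorrelation, storage decay, polar-group dependence)
but **not** real marginal distributions, measurement-protocol variation, or
genuine micelle physics: passing tests demonstrates that the pipeline
recovers a planted structure–loading relationship end-to-end, not that the
models transfer to laboratory data.

## Numerical choices and problem sizes

Seeds control every stochastic step (splits, Boruta shadows, CV folds,
downsampling, conformers, label permutations); two runs with one seed are
bit-identical. Tests and the acceptance script use reduced problem sizes —
tables of 120–600 rows, 5-fold CV with 1–2 repeats, tune lengths ≤ 3, forests
of 80–150 trees — as the package's own quick-run configuration
(`TrainConfig.quick()`); the full defaults above remain available.

## Known limitations

- The physicochemical backend is RDKit-based; descriptor names follow the
  mordred convention but 3D-MoRSE weighting blocks and the ESOL logS are this
  package's own implementations, so absolute values of those descriptors are
  not interchangeable with other engines.
- eeq/alp/H-bond-strength simplex labelings require externally supplied
  per-atom values.
- The pseudotrimer proxy ignores block-length effects on fragment counts
  (only the weighting sees them).
- Threshold ladders quantize predictions; estimates between rungs are
  reported at rung−1 % resolution by construction.
- Language-model embeddings and externally licensed fragment descriptors are
  out of scope.
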