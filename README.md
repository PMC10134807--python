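# pelagos

Community-assembly and co-occurrence analysis of depth-stratified marine
microbial communities — protists, free-living (FL) and particle-associated
(PA) bacteria sampled from the sunlit (photic, ≤ 200 m) down to the dark
(aphotic) ocean — packaged as a tested, reusable pipeline with a synthetic
metacommunity generator so every inference step can be verified by
parameter recovery without any sequencing data.

## Who this is for

Microbial ecologists asking *how much of community turnover down a water
column is selection versus drift and dispersal*, and *how co-occurrence
structure changes between photic and aphotic zones*. The pipeline starts
from a sample-by-OTU count table (TSV), sample metadata and an optional
phylogeny (newick), and covers:

* **Community variation** — Bray-Curtis dissimilarity (abundance- or
  presence/absence-based), PCoA, ANOSIM, PERMDISP, depth-decay regression
  of community similarity, and variation partitioning of community
  variation among four explanatory blocks (depth, dbMEM spatial
  eigenvectors, environment, biotic associations) via distance-based RDA
  with Ezekiel-adjusted R².
* **Assembly mechanisms** — Sloan's neutral community model
  `F(p) = 1 − Beta(d; N m p, N m (1 − p))` fitted by least squares in the
  single parameter `N m`; the checkerboard C-score
  `(R_i − S)(R_j − S)` with a fixed-row/fixed-column sequential-swap (sim9)
  null and `SES = (obs − null mean)/null SD`; and the phylogenetic null
  model combining weighted βNTI with RC_bray to classify each sample pair
  into heterogeneous selection, homogeneous selection, dispersal
  limitation, homogenizing dispersal, or undominated
  (|βNTI| > 2 → selection; else |RC| > 0.95 → dispersal; else undominated).
* **Niche and dispersal** — Levins' niche breadth `B_j = 1/Σ_i P_ij²`,
  community mean `B_com`, a pairwise shared-proportion dispersal proxy
  `2·min(n_i, n_k)/(n_i + n_k)`, and size-matched subsampled zone
  comparisons (Wilcoxon rank-sum).
* **Co-occurrence networks** — SparCC basis correlations with bootstrap
  pseudo-p values; edges at |r| ≥ 0.6 and BH-FDR p < 0.01; topology with
  Erdős–Rényi references; within-module degree z (Zi) and participation
  coefficient (Pi) keystone roles at the 2.50/0.62 thresholds; natural
  connectivity `ln((1/n) Σ e^{λ_j})` under targeted and random node
  removal; taxon-taxon-environment edge labelling; diversity-complexity
  regressions.

The synthetic generator (`pelagos.synthetic`) emulates the study design —
5 stations × 6–11 depths × 3 microbial groups — with controllable assembly
regime (neutral Sloan sampling, Gaussian niche filtering, or both),
Brownian trait conservatism on a simulated phylogeny, and planted basis
correlations, emitting ground truth with every table.

## Worked example

```python
from pelagos.synthetic import SimulationConfig, simulate_depth_transect_study
from pelagos.assembly import fit_sloan_ncm
from pelagos.ordination import anosim, bray_curtis

study = simulate_depth_transect_study(
    SimulationConfig(n_otus=200, n_reads_per_sample=2000, seed=42))
md = study.metadata
protist = study.tables["protist"]

r, p = anosim(bray_curtis(protist), md["zone"], n_perm=999, seed=0)
print(f"ANOSIM zone separation: R = {r:.2f}, p = {p:.3f}")

for zone in ("photic", "aphotic"):
    sub = protist.subset_samples(md.index[md.zone == zone]).drop_empty_otus()
    fit = fit_sloan_ncm(sub, n_boot=0)
    print(f"{zone}: NCM R^2 = {fit.r_squared:.3f}, m = {fit.m:.3f}")
```

prints

```
ANOSIM zone separation: R = 0.60, p = 0.001
photic: NCM R^2 = 0.618, m = 0.266
aphotic: NCM R^2 = 0.957, m = 0.167
```

The photic half of this simulation is assembled under environmental
filtering, the aphotic half neutrally — so the zones separate cleanly in
community space (R = 0.60, p = 0.001), and the neutral model describes the
aphotic communities far better (R² 0.96 vs 0.62), the direction observed
in real depth transects.

## The analysis

Numbered drivers under `analysis/` run the full study on synthetic data and
write tables under `results/`:

```bash
python analysis/01_simulate_transect.py    --seed 1   # data + ground truth
python analysis/02_community_structure.py  --seed 1   # PCoA/ANOSIM/VPA/decay
python analysis/03_assembly_mechanisms.py  --seed 1   # NCM, C-score, processes
python analysis/04_niche_dispersal.py      --seed 1   # Levins B, dispersal
python analysis/05_cooccurrence_networks.py --seed 1  # SparCC networks
```

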