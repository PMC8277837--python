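# Methods

`asmnet` contrasts gene co-expression between two conditions ("case" vs
"control") in small bulk RNA-seq studies. This note documents the models and
procedures, the choices made where the design was genuinely open, and the
limits of what the synthetic benchmarks demonstrate.

## Synthetic count generator (`simdata`)

The generator emulates a small case/control bulk RNA-seq design (default:
1,000 genes, 5 samples per condition, a configurable TF block) with three
planted signals.

**Latent layer.** Each co-expression module m has a per-sample standard
normal factor f_m. A target gene in module m gets latent value
√ρ·f_m + √(1−ρ)·ε, so target–target latent correlation is ρ
(`rho_within`, default 0.9) and regulator–target correlation is √ρ (the
regulator carries the factor itself). In rewired modules the **regulator's**
latent is replaced by independent noise in case samples only (or negated,
with `sign_flip=True`), destroying its correlation to the targets while
leaving target–target structure intact — the picture of a regulator
dropping out of its program. Genes outside modules are independent noise.

**Count layer.** Counts come from a Gaussian copula over negative-binomial
marginals: count = F⁻¹_NB(Φ(z)) where the NB mean combines a log-normal
baseline abundance (floor 5 counts at a 10⁶ library), a log-normal
library-size factor (σ = 0.2), and the planted fold change
2^(±`lfc_magnitude`) for DE genes in case samples; the NB variance is
μ + `nb_dispersion`·μ² (default dispersion 0.2, Poisson at 0). The copula
preserves the latent rank correlations under the count likelihood; the
monotone marginal transform leaves Pearson correlations of log counts within
a few percent of the latent values at realistic means.

**Planted DE.** A `de_fraction` of genes receive the fold change, drawn
first from the targets of rewired modules (`de_from_rewired=True`, the
default): a regulator losing its grip plausibly shifts its targets, and it
shifts them **coherently** — one sign is drawn per rewired module and shared
by its targets; DE genes outside rewired modules get independent random
signs. With no rewiring the selection degenerates to a uniform draw.

**What it does not emulate:** batch effects, gene length (units are CPM,
not TPM), isoform structure, count correlation induced by shared GC/mappability,
and real dispersion–mean trends. Calibration and recovery results below
therefore speak to the statistical machinery, not to any particular tissue.

Age and sex covariates are emitted with zero effect; they exercise the
design-matrix path without confounding the planted truth.

Everything is drawn from one `numpy` generator seeded by `seed`; identical
configuration gives byte-identical outputs.

## Filtering, normalization, differential expression (`preprocess`)

CPM = counts / library size × 10⁶. A gene is kept iff CPM ≥ 0.5 in at least
50% of samples (both thresholds configurable; the boundary convention — ≥,
following the usual `filterByExpr`-style reading — can be flipped with
`strict_boundary`). Expression is log2(CPM + 0.5); the prior count of 0.5 is
the standard pseudocount and configurable.

Differential expression is an ordinary per-gene linear model of log2-CPM on
condition plus optional centered age and a sex indicator, with a two-sided
t-test on the condition coefficient and Benjamini–Hochberg adjustment
(wrapping `statsmodels`) across all tested genes. This is deliberately a
simple, transparent DE stage: the downstream network analysis consumes only
the DEG list, and an externally computed DE table (e.g. from a
shrinkage-based NB model) can be supplied via `de_table` instead. Genes
constant across all samples get log2FC 0 and p = 1. DEGs are padj ≤ 0.1,
called up/down by the sign of log2FC.

## Regulatory impact factors (`rif`)

For DE gene j with condition means e1 (case), e2 (control): a = (e1+e2)/2,
dE = e1−e2, PIF = a·dE. For TF i with within-condition correlations r1, r2
to gene j and differential wiring DW = r1−r2:

    RIF1_i = (1/n_de) Σ_j PIF_j · DW_ij²
    RIF2_i = (1/n_de) Σ_j [(e1_j r1_ij)² − (e2_j r2_ij)²]

Raw scores are z-standardized across scored TFs (sample SD, ddof = 1);
significance is |z| ≥ 2 on either metric. Conventions: condition 1 = case;
a gene in both the TF and DEG lists contributes in both roles but its
self-pair is excluded (its correlation with itself is identically 1 and
would inject a spurious e1²−e2² term into RIF2); TFs constant within a
condition are dropped with a warning. Swapping the condition labels negates
both raw scores exactly — a symmetry asserted in tests.

## PCIT networks, hubs, scale-free fit (`pcit`)

For every gene trio (x, y, z) the first-order partial correlation
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) and the tolerance
ε = (r_xy·z/r_xy + r_xz·y/r_xz + r_yz·x/r_yz)/3 are computed; pair (x, y)
is eliminated if some z gives |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz|.
Numerical choices: legs are clipped to |r| ≤ 1−10⁻¹², a ratio term with a
zero denominator contributes 0, zero-variance genes are excluded from trios
and pairs. The vectorized implementation (one z at a time, whole-matrix
operations, exploiting r_yz·x = r_xz·yᵀ) is arithmetically identical to the
O(n³) definition and is tested pair-for-pair against an independent
triple-loop oracle.

The reporting network keeps PCIT-surviving pairs with |r| ≥ 0.95, a
per-edge correlation t-test p < 0.05 (t = r√((n−2)/(1−r²)), df = n−2; at
n = 5 this test is the only place sample size enters the edge filter), and
at least one endpoint in the anchor set (DEGs ∪ significant TFs, or all TFs
with `anchor_all_tfs`). Degrees are computed on this post-filter network.

Hubs: degree strictly greater than mean + 2·SD (sample SD). Note that in a
network of n nodes a single outlier can reach at most (n−1)/√n sample SDs
above the mean, so tiny networks cannot have hubs under this rule — the
rule is meant for networks of hundreds of nodes.

Scale-free fit: degrees are binned into 10 log-spaced bins (WGCNA-style),
P(k) per nonempty bin is regressed as log10 P(k) on the bin's mean log10
degree, and R² is reported; fewer than 3 nonempty bins gives NaN with a
warning. An exact power-law degree sequence yields R² = 1 by construction.

## Union network and differential connectivity (`rewiring`)

Case and control edge lists are merged into a central reference network with
case_only/control_only/shared flags on nodes and edges. Per gene,
K = k/max(k) within each condition (genes absent from one network count
k = 0 there, which is what makes DK well-defined on the union set), and
DK = K_case − K_control ∈ [−1, 1]. DK is z-scored over all union genes
(mean-centered, sample SD; both choices exposed as `center` and `ddof`
since the ±1.96 SD rule does not pin them down) and genes with z ≥ 1.96 /
z ≤ −1.96 are gains / losses. Condition swap negates DK and z exactly and
flips every call.

## Differential correlation (`diffcorr`)

For each pair, z = atanh(r) per condition and
z_diff = (z_case − z_control)/√(1/(n_case−3) + 1/(n_control−3)), two-sided
normal p, BH over all tested pairs. Each side of a pair is classed '+'
(r > 0, correlation t-test p ≤ 0.05), '−' (r < 0, p ≤ 0.05) or '0',
giving the nine case/control classes +/+ … 0/−, which partition all pairs.
The per-condition class alpha of 0.05 follows the usual differential-
correlation convention. Scanning is blocked (default 512 genes per block)
so the all-pairs universe stays memory-bounded; the anchored universe is the
pipeline default. At 5 samples per group 1/(n−3) = 0.5 per condition and
the test has very little power; a warning is emitted below 10 per group.

## Over-representation and marker intersection (`enrich`)

One-sided hypergeometric tail P(X ≥ overlap) per term against a declared
universe (default: all genes surviving the CPM filter), BH across terms;
both raw and adjusted p are emitted since pathway screens are often gated
on the raw value. Redundant significant terms are grouped by Cohen's kappa
of their query-membership indicator vectors (computed over the query genes
only), single-linkage over pairs with kappa ≥ 0.4, with deterministic group
numbering by lexicographically smallest member. Degenerate kappa (both
vectors constant) is defined as 1 for identical vectors, else 0. Marker
intersection is an exact, case-normalized set intersection reported with
both set sizes. No annotation databases are bundled; gene sets are
user-supplied GMT files.

## Pipeline (`pipeline` / `asmnet` CLI)

Stage order: simulate-or-load → CPM filter → normalize → DE → RIF → anchors
→ per-condition PCIT networks (edges, SIF, hubs, scale-free R²) → union +
DK → anchored differential-correlation scan → optional ORA and marker
intersection. A JSON manifest records input/output SHA-256 hashes, row
counts and wall times per stage; re-running with the same seed reproduces
every output byte-for-byte (timings aside). All thresholds (alpha_de 0.1,
rif_z 2, r_min 0.95, alpha_r 0.05, dk_z 1.96, alpha_adj 0.05, class_alpha
0.05, kappa 0.4, cpm 0.5, frac 0.5) are config fields.

## Benchmark problem sizes

The default synthetic scenario is 1,000 genes with 5 samples per condition
— the study design the package targets, at a genome scale where the O(n³)
PCIT scan completes in seconds to tens of seconds on one core. The recovery
benchmarks use: 200 genes / 4 modules of 20 / 20 per group at ρ = 0.98 for
differential-connectivity recovery; 200 genes / 1 module of 10 at ρ = 0.81
(regulator–target r ≈ 0.9) with 25 per group for RIF recovery, sized so the
planted regulator's |RIF1 z| ≥ 2 with comfortable power; 10,000 independent
null pairs and 5,000 planted pairs at 20 per group for the Fisher-z
calibration and power checks. Blocked PCIT evaluation over larger gene sets
is supported by the same kernel (it is a loop over conditioning genes), at
cubic cost.

## Known limitations

* The DE stage is an OLS on log-CPM, not a count-likelihood model; at very
  small n or very low counts its p-values are approximate.
* CPM is a total-count normalization and is therefore composition-
  sensitive: strongly asymmetric planted DE inflates the case library total
  and deflates every other gene's CPM, which a well-powered design (say 20
  per group) will flag as weak global down-regulation. Median-of-ratios or
  TMM-style factors would remove this; they are out of scope here, and the
  network stages — which consume correlations, not fold changes — are
  unaffected.
* With 5 samples per condition the |r| ≥ 0.95 edge filter and the Fisher-z
  test both operate at the edge of what the sample size supports; results
  at that scale are exploratory by construction, and the warnings say so.
* The kappa grouping reproduces term-redundancy clustering only; no
  ontology-aware filtering or two-sided enrichment/depletion mode.
* Hub and DK calls depend on the anchor set: they are statements about the
  anchored network, not the full transcriptome graph.
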