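# Methods

`netsel` implements a network-level molecular-evolution analysis of a
signaling cascade: per-gene selection pressure is estimated with codon
substitution models, codon-usage bias with the effective number of
codons, and the relationship between selection and pathway architecture
(position along the cascade, protein–protein-interaction degree,
protein length, codon bias) with rank correlations, partial
correlations and path analysis. The package ships the reference table
of 50 TLR-signaling-pathway genes from eight vertebrates that the
statistical layer is calibrated against.

## Codon substitution model

The engine is the Goldman–Yang codon model over the 61 sense codons of
the standard genetic code. The instantaneous rate from codon *i* to
*j* is zero unless the codons differ at exactly one nucleotide, and
otherwise

q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

with π the stationary codon frequencies, κ the
transition/transversion rate ratio and ω = dN/dS the
nonsynonymous/synonymous rate ratio. The generator is scaled so one
time unit equals one expected substitution per codon at stationarity;
branch lengths are therefore substitutions per codon. Frequencies
default to F3x4 (products of position-specific nucleotide frequencies,
renormalized over sense codons), with F61 (empirical codon
frequencies) available. Frequencies are floored at 1e-10 to keep the
chain irreducible when a codon is unobserved.

Site-class models place a mixture of ω values over sites: M0 (one
ratio), M1a (p0 with ω0 ≤ 1, rest neutral), M2a (adds a class with
ω2 ≥ 1), M7 (beta-distributed ω discretized into K = 10
equal-probability classes, each represented by its class mean computed
from the incomplete beta function), M8 (beta plus a selection class
ω_s ≥ 1) and M8a (ω_s pinned at 1). All classes of a mixture share a
single normalization — the mixture-averaged rate is one substitution
per codon — so branch lengths are comparable across models. The
two-ratio branch model instead assigns a distinct ω to designated
branches; there each branch's generator is normalized by its own rate.

Likelihoods are computed by Felsenstein pruning with site-pattern
compression and per-pattern log scaling. Transition matrices come from
the eigendecomposition of the symmetrized reversible generator
(D^{1/2} Q D^{-1/2}), which makes P(t) for all branches a cheap
byproduct of one 61×61 `eigh`; a scaling-and-squaring `expm` path
backs the public `transition_probabilities` function. Gap or
ambiguous codons are missing data (partial likelihood of ones);
in-frame stop codons are rejected by default or, with `mask_stops`,
the whole column is excluded. Under a reversible model the likelihood
is root-invariant, so unrooted (trifurcating) trees are handled by
rooting at the basal node.

## Fitting

Branch lengths and model parameters are maximized jointly with
L-BFGS-B after transforming every constrained parameter to an
unconstrained scale: logs for branch lengths (bounds 1e-6 to 20),
κ, ω and beta shapes; logits for proportions in [0, 1]; a softmax for
the M2a simplex; 1 + exp(·) for ω classes constrained above 1.
Initial values are 0.1 for branch lengths, κ = 2 and mild defaults per
model. The default is a single deterministic start — on the surfaces
exercised here it converges reliably and keeps the simulation studies
affordable — with `n_starts` enabling seeded random restarts for
multimodal site-model surfaces. Convergence follows L-BFGS-B's
relative function tolerance (1e-11, i.e. |ΔlnL| well below 1e-6 at
typical magnitudes); failures return `converged=False` rather than
raising. Alignments with no variation drive all branch lengths to the
lower bound and are flagged non-identifiable.

The dn/ds decomposition of an M0 fit follows the substitution-flow
convention: with the normalized generator, ρ_N = Σ_{nonsyn} π_i q_ij
is the nonsynonymous share of substitution flow; the site proportions
p_N, p_S come from the same matrix with ω = 1; then
dn = T·ρ_N/(3p_N) and ds = T·ρ_S/(3p_S) with T the tree length. This
makes dn/ds ≡ ω̂ by construction (the reference table reports
tree-total dn and ds, with values well above 1, consistent with this
convention). When ds = 0 the ratio is reported as NaN, never infinity.

Nested models are compared with likelihood-ratio tests: 2ΔlnL against
χ² with 2 df (M1a–M2a, M7–M8) or 1 df (M8a–M8). The statistic is
clipped at zero and a worse alternative likelihood triggers a warning.
For M8a–M8 the plain χ²(1) tail is used; the 50:50 boundary mixture
correction is deliberately not applied, which makes the test
conservative. The M1a–M2a null distribution is also conservative
because the extra parameters sit on the boundary under the null — the
calibration check therefore requires the type-I rate to be at most
0.08 at nominal 0.05, and observed rates are typically well below.

## Codon-usage bias

Wright's effective number of codons. Per synonymous family with total
count n and proportions p_i, homozygosity is
F̂ = (nΣp_i² − 1)/(n − 1); ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆
with F̄_k the mean over families of size k (Met and Trp give the
constant 2), clipped to [20, 61]. Families with n < 2 or F̂ ≤ 0 are
undefined and borrow the mean of observed same-size families; an
entirely missing three-fold class (Ile) is interpolated as
(F̄₂ + F̄₄)/2; any other empty size class falls back to the neutral
1/k. A gene's codon-bias summary across species is the median ENC.
The companion "% used codons" statistic defaults to the share of the
61 sense codons observed at least once; the observation threshold is
configurable because published variants of this statistic differ.

## Statistics over the gene table

Spearman correlations use mid-ranks with the t-approximation p-value
on n − 2 df. Partial correlations use the residual method: x and y
are regressed (with intercept) on the controls and the residuals
correlated, with n − |controls| − 2 df; a rank variant first mid-ranks
every column. Path analysis fits each endogenous variable of a
user-declared DAG by OLS on standardized (z-scored) values, so slopes
are standardized path coefficients β; effects decompose into the
direct edge plus the sum over directed paths of products of β. The
default convention for partials and paths is Pearson on raw values —
with the packaged table it reproduces the published coefficients to
within ±0.02, while the rank convention departs by up to 0.1 — and
both conventions are exposed.

The shipped causal model treats position, protein length and
connectivity as exogenous; ENC ← {position, length},
dn ← {position, length, ENC} and ω ← {dn, position, ENC, length} are
the endogenous equations.

## Orthology rules

Decision procedure over precomputed tabular similarity hits (no search
program is executed). Hits must exceed score 150 and alignment length
50 (strict inequalities). A query is an ortholog when the top-scoring
hits of the two reciprocal searches match (ties broken by similarity,
then lexicographic subject id, making the verdict order-independent);
otherwise the surviving hit with the best query coverage can rescue a
homolog call if it clears score > 150, identity > 30% and
similarity > 40%; otherwise non-homolog, or absent when nothing
survives filtering. Verdict counts aggregate into a gene × genome
copy-number matrix with a 0/1 presence flag.

## Synthetic data

The feature-table generator is a Gaussian copula: a target Spearman
matrix is converted to the normal scale (r = 2 sin(πρ/6)), checked for
positive semidefiniteness, sampled as a multivariate normal and pushed
through per-column inverse CDFs. Default marginals mimic the
reference table: positions uniform on 1–8, protein length uniform on
220–1050, zero-inflated geometric connectivity, ENC uniform on 41–57,
ω log-uniform on 0.005–0.3; count-like columns are rounded.

The pathway scenario emulates the study design at desk scale: 40 genes
(5 per position 1–8), a five-taxon tree of total length ≈ 0.86
substitutions per codon, 200 codons per gene, κ = 2, and a linear ω
gradient from 0.25 upstream to 0.02 downstream with multiplicative
lognormal noise (σ = 0.25), which keeps ω positive. These sizes are
the package's defaults for a laptop-scale rehearsal; they are smaller
than the eight-genome, full-length-CDS design they imitate, so the
rehearsal demonstrates that the pipeline detects a position–ω gradient
of realistic strength, not that it reproduces any particular gene's
estimate. What the generators do not emulate: indels and alignment
error, among-gene tree heterogeneity, codon-frequency biases beyond
F3x4, and real PPI-network topology.

## Numerical choices and limitations

Likelihood agreement with exhaustive ancestral-state enumeration is
required to 1e-8 on three-taxon toys; transition-probability rows sum
to one within 1e-10 with negatives clipped at zero. The copula
generator refuses non-PSD targets and suggests the nearest PSD
correlation matrix (eigenvalue clipping). Reported p-values are
two-sided and uncorrected for multiple testing, matching the analysis
convention the package reproduces. Exact numerical parity with other
codon-model implementations is not promised — model-definition parity
is: conventions such as F3x4 estimation detail, beta-class
representation and optimizer path differ between programs and shift
estimates within sampling error. Bayes empirical Bayes site
identification, amino-acid models and tree search are out of scope.
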