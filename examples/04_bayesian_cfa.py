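"""Bayesian confirmatory factor analysis with Gibbs sampling.

Fits the two-factor confirmatory model (each trait loads on exactly one
factor; marker identification fixes the anchor trait's raw loading at 1),
sampling factor scores by data augmentation.  Reports standardized loadings
with posterior SDs, the Gelman-Rubin convergence diagnostic, and the
posterior-mean factor scores that become the "difficult" and "easy"
phenotypes of the genetic analysis.
"""

from cattletemp import cfa
from cattletemp.efa import FactorStructure
from cattletemp.synthetic import REFERENCE_LOADINGS, simulate_measurement_observations

T = simulate_measurement_observations(n=1528, seed=4)
structure = FactorStructure(
    {trait: factor for trait, (factor, _) in REFERENCE_LOADINGS.items()},
    ["difficult", "easy"], {"difficult": "ts", "easy": "calm"})

samples = cfa.fit_bayesian_cfa(T, structure, n_chains=3, n_iter=6000,
                               n_burnin=3000, seed=4)

table = cfa.standardize_loadings(samples)
table["generating"] = table["trait"].map(
    {t: lam for t, (_, lam) in REFERENCE_LOADINGS.items()})
print(table.round(3).to_string(index=False))

diag = cfa.monitored_psrf(samples)
print(f"\nmax PSRF over monitored parameters: {diag.max():.3f} "
      f"(convergence threshold 1.2)")

scores = cfa.extract_factor_scores(samples)
print("\nposterior-mean factor scores (first animals):")
print(scores.head().round(3).to_string())
# Posterior-mean standardized loadings land within a few hundredths of the
# generating values, with posterior SDs smallest for the strongest loadings;
# a PSRF near 1 says the three chains agree.
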