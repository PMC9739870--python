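"""Rank the candidate mixed models for body size and multivariate shape.

Five candidates explain AG (axilla-groin distance): species or site typology
as the single fixed factor (never crossed), with or without a population
random intercept.  Eleven candidates explain the eight other body features,
optionally with AG as an allometric covariate.  Models are compared by AICc;
the Akaike weight is the probability a model is the best of its set.
"""

from salamorph.biometry import collinearity_screen, rank_models
from salamorph.synthetic import SyntheticDesign, generate_biometric_dataset

biom = generate_biometric_dataset(SyntheticDesign(seed=0))

print("collinearity screen (size proxies vs AG; |r| > 0.85 are excluded):")
print(collinearity_screen(biom).round(3).to_string(index=False))

ag = rank_models(biom, response="AG")
print("\nbody size (AG) candidate models, best first:")
print(ag[["model", "AICc", "delta", "weight", "p_value"]].round(3).to_string(index=False))
print("(the habitat + population-intercept model should rank above the "
      "fixed-only models: habitat matters once population variation is absorbed)")

shape = rank_models(biom, response="shape")
print("\nmultivariate shape candidate models (8 z-scored features, summed fits):")
print(shape[["model", "AICc", "delta", "weight", "p_value"]].round(3).to_string(index=False))
print("(models carrying AG as covariate dominate: shape variation is allometric)")
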