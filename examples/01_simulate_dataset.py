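"""Generate a synthetic five-population *Salamandrina* dataset.

Builds the biometric table (11 measurements, mm) and the head dataset
(33-point landmark configurations + binary V-patch images) under the default
study design: 156 females from 5 sites, lentic animals larger than brook
ones, and two habitat-associated latent colour-pattern clusters.
"""

import numpy as np

from salamorph.synthetic import SyntheticDesign, generate_biometric_dataset, generate_head_dataset

design = SyntheticDesign(seed=0)
biom = generate_biometric_dataset(design)
records, rasters, labels = generate_head_dataset(design, grid=(128, 128))

print("biometric table:", biom.shape[0], "individuals x", biom.shape[1], "columns")
print("\nAG (axilla-groin, mm) by population:")
print(biom.groupby(["population", "species", "site_typology"])["AG"].mean().round(2))
print("\nr(SVL, AG) =", np.corrcoef(biom["SVL"], biom["AG"])[0, 1].round(3),
      " (size proxies are nearly collinear with AG, hence excluded from modelling)")
print("\nhead dataset:", len(records), "landmark records,",
      f"{rasters[0].shape[0]}x{rasters[0].shape[1]} px binary images")
print("latent pattern clusters by habitat (the design plants a 0.9 association):")
print(labels.groupby(["site_typology", "cluster"]).size())
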