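"""Per-sample geolocation uncertainty from a SNP-resampling bootstrap.

Each pseudoreplicate resamples loci with replacement, retrains the
regressor from scratch, and predicts the held-out samples; the
per-sample prediction cloud is summarized by its centroid and the
50/90/95% quantile radii of distance from the centroid.
"""

import numpy as np

from geoloci import (
    FeatureMatrix,
    LandscapeSim,
    ModelSpec,
    TrainConfig,
    bootstrap_predict,
    cluster_coordinates,
    resolve_width,
    simulate_ibd,
    stratified_split,
)
from geoloci.io import doses_to_features

G, C, _ = simulate_ibd(LandscapeSim(seed=1, n_samples=150, n_loci=120))
F = doses_to_features(G)
clus = cluster_coordinates(C, seed=1)
split = stratified_split(C, clus, seed=1)
tr, va, te = split.train, split.validation, split.test[:5]

spec = ModelSpec(input_dim=F.n_features,
                 resolved_width=resolve_width(256, len(tr), F.n_features))
cfg = TrainConfig(max_epochs=300, patience=30, seed=1)
results = bootstrap_predict(
    FeatureMatrix(C.sample_ids[tr], F.values[tr]), C.subset(tr),
    FeatureMatrix(C.sample_ids[va], F.values[va]), C.subset(va),
    FeatureMatrix(C.sample_ids[te], F.values[te]), spec, cfg,
    n_boot=10, seed=1, truths=C.subset(te),
)

print(f"{'sample':>8} {'centroid lon':>12} {'lat':>8} {'r90 km':>8} "
      f"{'err km':>8} {'covered':>8}")
for i, (sid, r) in zip(te, results.items()):
    cov = r.covers(C.lon[i], C.lat[i], 0.9)
    print(f"{sid:>8} {r.centroid[0]:12.4f} {r.centroid[1]:8.4f} "
          f"{r.quantile_radii_km[0.9]:8.1f} {r.error_km:8.1f} {str(cov):>8}")
# r90 is the radius holding 90% of the bootstrap cloud around the
# centroid; 'covered' says whether the 90% ellipse contains the truth.
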