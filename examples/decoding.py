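"""Single-trial decoding of concepts from pre-onset gaze position.

Small-vs-large numbers are decoded from the horizontal coordinate with a
balanced leave-one-trial-out LDA and a label-permutation test; a densely
sampled color subject (many blocks) then shows pairwise color decoding and
the growth of accuracy with ring distance.
"""

import numpy as np
import pandas as pd

from gazegeom import conceptspace, decode, gazeprep, synthgaze

# -- numbers: small (1-6) vs large (7-12) from horizontal gaze -------------
geom = synthgaze.LatentGeometry.number_line()
cfg = synthgaze.SessionConfig(domain="number", n_trials=120, coupling=6.5,
                              noise_sd=85.0, drift_sd=2.0, seed=11)
sess = synthgaze.generate_session(cfg, geom)
trials = gazeprep.window_median_gaze(sess.recording, sess.events)
v = trials[trials["valid"]]
res = decode.permutation_pvalue(v["median_x_px"].to_numpy(float),
                                decode.small_large_labels(v["word"]),
                                n_perm=1000, seed=5)
print(f"small/large decoding: accuracy = {res.observed_accuracy:.3f}, "
      f"permutation p = {res.p_perm:.3f} "
      f"(null mean {res.permuted_accuracies.mean():.3f})")

# -- colors: pairwise decoding on a dense subject (8 blocks here) ----------
cgeom = synthgaze.LatentGeometry.color_ring()
affine = synthgaze.random_isometry_affine(np.random.default_rng(21),
                                          scale=1.0, center=(960, 540))
ccfg = synthgaze.SessionConfig(domain="color", n_trials=90, coupling=150.0,
                               noise_sd=85.0, drift_sd=2.0, affine=affine,
                               seed=21)
sessions = synthgaze.simulate_subject(ccfg, cgeom, n_blocks=8)
ctrials = pd.concat([gazeprep.window_median_gaze(s.recording, s.events)
                     for s in sessions], ignore_index=True)
acc = decode.pairwise_color_decoding(ctrials, seed=3)
labels = list(acc.labels)
pts = cgeom.coord_array(labels)
dm = conceptspace.DissimilarityMatrix(
    tuple(labels), np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
rho, slope = decode.accuracy_vs_distance(acc, dm)
print(f"pairwise color decoding: overall accuracy = {acc.overall:.3f}")
print(f"accuracy vs ring distance: rho = {rho:.2f}, "
      f"slope = {slope:.3f} accuracy per unit chord")
print("-> nearby hues are confusable from gaze alone; distant hues are not,")
print("   exactly what a ring-shaped representational geometry predicts.")
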